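"""Analysis of the intermittent regime.

Tools for the three classical signatures of type-1 (tangent-bifurcation)
intermittency: a first-return map of successive oscillation maxima that
hugs the diagonal in a narrow channel, long "laminar" phases — here the
high-amplitude rhythm identified with seizure activity — whose duration
distribution is U-shaped, and the divergence of mean passage times as the
coupling approaches the locking onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import Trajectory

__all__ = [
    "ReturnMap",
    "LaminarPhases",
    "extract_maxima",
    "return_map",
    "tangency_gap",
    "segment_laminar",
    "duration_ushape",
    "episode_counts",
]


@dataclass(frozen=True)
class ReturnMap:
    """Ordered successive-extremum sequence for one observable."""

    values: np.ndarray
    observable: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 2:
            raise ValueError("need at least two extrema to form a return map")

    def pairs(self) -> np.ndarray:
        """(K-1, 2) array of consecutive pairs (m_k, m_{k+1})."""
        return np.column_stack([self.values[:-1], self.values[1:]])

    def save(self, path) -> None:
        np.savetxt(
            path,
            self.pairs(),
            delimiter="\t",
            header=f"m_k\tm_k+1 ({self.observable})",
        )


@dataclass(frozen=True)
class LaminarPhases:
    """High-amplitude episodes of one compartment.

    ``episodes`` is an (n, 2) array of (start, end) times; durations are
    strictly positive and episodes are disjoint and time-ordered.
    """

    episodes: np.ndarray
    threshold: float
    compartment: int = 0

    def __post_init__(self) -> None:
        ep = np.asarray(self.episodes, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "episodes", ep)
        if ep.size and (
            np.any(np.diff(ep, axis=1) <= 0)
            or np.any(np.diff(ep.ravel()) < 0)
        ):
            raise ValueError("episodes must be ordered, disjoint, positive-length")

    @property
    def durations(self) -> np.ndarray:
        return self.episodes[:, 1] - self.episodes[:, 0]

    @property
    def n_episodes(self) -> int:
        return self.episodes.shape[0]

    def save(self, path) -> None:
        data = np.column_stack([self.episodes, self.durations])
        np.savetxt(
            path,
            data,
            delimiter="\t",
            header=f"start\tend\tduration (r>{self.threshold})",
        )


def extract_maxima(
    values: np.ndarray, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima of a sampled signal, quadratically refined.

    Fits a parabola through each sample triple bracketing a discrete
    maximum, which removes most of the sampling-grid quantisation.
    Boundary samples never count.  Returns ``(t_peaks, v_peaks)``.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size != t.size:
        raise ValueError("values and times must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 samples to locate interior maxima")
    left, mid, right = v[:-2], v[1:-1], v[2:]
    idx = np.nonzero((mid >= left) & (mid > right))[0] + 1
    # flat-topped plateaus keep only their first sample via >= / > asymmetry
    t_pk = np.empty(idx.size)
    v_pk = np.empty(idx.size)
    for k, i in enumerate(idx):
        y0, y1, y2 = v[i - 1], v[i], v[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper curvature: refine
            delta = 0.5 * (y0 - y2) / denom
            delta = np.clip(delta, -0.5, 0.5)
            dt = t[i + 1] - t[i] if delta > 0 else t[i] - t[i - 1]
            t_pk[k] = t[i] + delta * dt
            v_pk[k] = y1 - 0.25 * (y0 - y2) * delta
        else:
            t_pk[k] = t[i]
            v_pk[k] = y1
    return t_pk, v_pk


def return_map(maxima: np.ndarray, observable: str = "") -> ReturnMap:
    """First-return map of an ordered extremum sequence."""
    maxima = np.asarray(maxima, dtype=float)
    if maxima.size < 2:
        raise ValueError("need at least two extrema")
    return ReturnMap(maxima, observable)


def tangency_gap(
    rm: ReturnMap, window: tuple[float, float]
) -> tuple[float, bool]:
    """Closest signed approach of the return map to the diagonal.

    Considers pairs whose first coordinate m_k lies in ``window`` and
    returns ``(gap, crossed)``: ``gap`` is the signed distance
    min(m_{k+1} - m_k) (positive when the map stays above the diagonal)
    of smallest magnitude, and ``crossed`` reports whether the map crosses
    the diagonal inside the window.  A small positive gap with no crossing
    is the near-tangent channel of type-1 intermittency.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must be a nonempty interval")
    pairs = rm.pairs()
    inside = (pairs[:, 0] >= lo) & (pairs[:, 0] <= hi)
    if not inside.any():
        raise ValueError("no return-map pairs inside the window")
    diffs = pairs[inside, 1] - pairs[inside, 0]
    gap = diffs[np.argmin(np.abs(diffs))]
    crossed = diffs.min() < 0 < diffs.max() or np.any(diffs == 0)
    return float(gap), bool(crossed)


def segment_laminar(
    traj: Trajectory,
    compartment: int,
    r_threshold: float = 1.5,
    min_duration: float | None = None,
) -> LaminarPhases:
    """High-amplitude (laminar) episodes of one compartment.

    Episodes are maximal intervals with r(t) > ``r_threshold``; crossing
    times are linearly interpolated between samples, and episodes shorter
    than ``min_duration`` (default: one fast rotation period 2*pi/omega,
    taken from the trajectory) are discarded as threshold-grazing
    artefacts.  The default threshold 1.5 is the midpoint of the two
    saddle-node radii r=1 and r=2 of the default amplitude curve.
    """
    r = traj.r(compartment)
    t = traj.times
    if not 0 < r_threshold:
        raise ValueError("threshold must be positive")
    if r_threshold >= float(np.max(r)) and not np.any(r > r_threshold):
        return LaminarPhases(np.empty((0, 2)), r_threshold, compartment)
    if min_duration is None:
        min_duration = traj.fast_period()
    above = r > r_threshold
    episodes: list[tuple[float, float]] = []
    start: float | None = t[0] if above[0] else None
    for i in range(1, t.size):
        if above[i] and not above[i - 1]:
            # upward crossing between i-1 and i
            frac = (r_threshold - r[i - 1]) / (r[i] - r[i - 1])
            start = t[i - 1] + frac * (t[i] - t[i - 1])
        elif not above[i] and above[i - 1] and start is not None:
            frac = (r_threshold - r[i - 1]) / (r[i] - r[i - 1])
            end = t[i - 1] + frac * (t[i] - t[i - 1])
            episodes.append((start, end))
            start = None
    if start is not None and above[-1]:
        episodes.append((start, float(t[-1])))
    keep = [(s, e) for s, e in episodes if e - s >= min_duration]
    return LaminarPhases(
        np.array(keep).reshape(-1, 2), r_threshold, compartment
    )


def duration_ushape(
    durations: np.ndarray, n_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, bool | None]:
    """Histogram of laminar durations and a simple U-shape verdict.

    Returns ``(counts, bin_edges, is_u_shaped)``.  The verdict is True iff
    both end bins strictly exceed every interior bin — the end-heavy
    profile characteristic of type-1 laminar lengths — and None when fewer
    than 20 durations are available (histogram only; the shape test is
    then statistically meaningless).
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("no durations to histogram")
    counts, edges = np.histogram(durations, bins=n_bins)
    if durations.size < 20 or n_bins < 3:
        return counts, edges, None
    interior_max = counts[1:-1].max()
    verdict = bool(counts[0] > interior_max and counts[-1] > interior_max)
    return counts, edges, verdict


def episode_counts(phases: list[LaminarPhases]) -> np.ndarray:
    """Episode count per compartment from per-compartment segmentations."""
    return np.array([p.n_episodes for p in phases])
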