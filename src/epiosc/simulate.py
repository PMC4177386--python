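"""Numerical integration of the coupled network and beta-sweep machinery.

The coupled system is stiff-free but carries a fast rotation, so an
adaptive Runge-Kutta (scipy's RK45 via ``solve_ivp``) with output sampled
on a uniform grid fine enough to resolve the fast period is used
throughout.  Sweeps over the coupling strength beta continue the attractor
by re-using the final state of one beta value as the initial condition of
the next, which is what exposes hysteresis between forward and backward
scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .oscillator import CompartmentParams, limit_cycle_amplitudes
from .networks import Adjacency

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "BifurcationDiagram",
    "IntegrationError",
    "initial_state",
    "integrate",
    "sweep_beta",
    "find_intermittency_onset",
    "is_locked",
]


class IntegrationError(RuntimeError):
    """Raised when the state leaves the finite range during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one integration run.

    ``t_transient`` is discarded from analyses but still integrated;
    ``sample_dt`` must resolve the fast oscillation (at least ~20 samples
    per period 2*pi/omega; the default gives ~36 per period at the
    package default omega=3.5).
    ``initial_policy`` is one of "on-small-cycles" (each compartment starts
    on its uncoupled stable small-amplitude orbit at a seeded random
    phase), "random-small" (small random Cartesian state), or "explicit"
    (caller passes the state to :func:`integrate`).
    """

    t_end: float = 2000.0
    t_transient: float = 100.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    sample_dt: float = 0.05
    initial_policy: str = "on-small-cycles"
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (0 <= self.t_transient < self.t_end):
            raise ValueError("need 0 <= t_transient < t_end")
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.sample_dt <= 0:
            raise ValueError("tolerances and sample_dt must be positive")
        if self.initial_policy not in (
            "on-small-cycles",
            "random-small",
            "explicit",
        ):
            raise ValueError(f"unknown initial policy {self.initial_policy!r}")


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of the coupled system.

    ``x`` and ``y`` are (n_times, n_compartments) arrays on the strictly
    increasing grid ``times``.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    beta: float
    config: SimulationConfig | None = None
    omega: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_compartments(self) -> int:
        return self.x.shape[1]

    def r(self, compartment: int | None = None) -> np.ndarray:
        """Instantaneous radius sqrt(x^2+y^2), all compartments or one."""
        if compartment is None:
            return np.sqrt(self.x**2 + self.y**2)
        return np.sqrt(
            self.x[:, compartment] ** 2 + self.y[:, compartment] ** 2
        )

    def after(self, t0: float) -> "Trajectory":
        """Sub-trajectory with times >= t0 (transient removal)."""
        keep = self.times >= t0
        return Trajectory(
            self.times[keep], self.x[keep], self.y[keep], self.beta,
            self.config, self.omega,
        )

    def fast_period(self) -> float:
        """Base rotation period 2*pi/omega (2*pi when omega is unknown)."""
        return 2.0 * np.pi / self.omega if self.omega else 2.0 * np.pi

    def final_state(self) -> np.ndarray:
        return np.concatenate([self.x[-1], self.y[-1]])

    def save(self, path) -> None:
        """One row per sample: t, x_1..x_N, y_1..y_N (tab-delimited)."""
        data = np.column_stack([self.times, self.x, self.y])
        n = self.n_compartments
        header = "t\t" + "\t".join(
            [f"x{i + 1}" for i in range(n)] + [f"y{i + 1}" for i in range(n)]
        )
        np.savetxt(path, data, delimiter="\t", header=header)


@dataclass(frozen=True)
class BifurcationDiagram:
    """Distinct-maxima summary of a beta sweep in one direction."""

    betas: np.ndarray
    maxima: list[np.ndarray]
    direction: str
    observable: str = "x"
    compartment: int = 2
    failed: list[bool] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        """Number of distinct maxima at each beta."""
        return np.array([m.size for m in self.maxima])

    def save(self, path) -> None:
        """(beta, maximum) pairs, one per row, tab-delimited."""
        rows = [
            (b, m)
            for b, ms in zip(self.betas, self.maxima)
            for m in np.atleast_1d(ms)
        ]
        np.savetxt(
            path,
            np.array(rows) if rows else np.empty((0, 2)),
            delimiter="\t",
            header=f"beta\tmax_{self.observable}{self.compartment + 1}"
            f" ({self.direction})",
        )


def _uncoupled_small_radius(p: CompartmentParams) -> float:
    """Radius of the uncoupled stable small-amplitude orbit (or ~0)."""
    branches = [
        (R, lab) for R, lab in limit_cycle_amplitudes(p.mu, p) if lab == "stable"
    ]
    if not branches:
        return 0.05  # below the Hopf: rest state, start near the origin
    return float(np.sqrt(min(R for R, _ in branches)))


def initial_state(
    params: Sequence[CompartmentParams], config: SimulationConfig
) -> np.ndarray:
    """Initial condition vector (x_1..x_N, y_1..y_N) under the config policy."""
    n = len(params)
    rng = np.random.default_rng(config.seed)
    if config.initial_policy == "on-small-cycles":
        phases = rng.uniform(0.0, 2.0 * np.pi, n)
        radii = np.array([_uncoupled_small_radius(p) for p in params])
        return np.concatenate(
            [radii * np.cos(phases), radii * np.sin(phases)]
        )
    if config.initial_policy == "random-small":
        return 0.1 * rng.standard_normal(2 * n)
    raise ValueError(
        "explicit initial policy requires an explicit state argument"
    )


def _rhs_factory(
    params: Sequence[CompartmentParams],
    A: Adjacency | np.ndarray,
    beta: float,
    coupling: str = "absolute",
) -> Callable[[float, np.ndarray], np.ndarray]:
    W = A.weights if isinstance(A, Adjacency) else np.asarray(A, dtype=float)
    n = len(params)
    if W.shape != (n, n):
        raise ValueError(
            f"adjacency shape {W.shape} does not match {n} compartments"
        )
    if np.any(np.diagonal(W) != 0):
        raise ValueError("adjacency must have zero diagonal")
    if coupling not in ("absolute", "degree-normalized"):
        raise ValueError(f"unknown coupling convention {coupling!r}")
    if coupling == "degree-normalized":
        deg = W.sum(axis=1)
        deg[deg == 0] = 1.0  # isolated node: no coupling either way
        W = W / deg[:, None]
    mu = np.array([p.mu for p in params])
    a = np.array([p.a for p in params])
    b = np.array([p.b for p in params])
    c = np.array([p.c for p in params])
    omega = np.array([p.omega for p in params])
    d = np.array([p.d for p in params])
    bW = beta * W

    def rhs(t: float, s: np.ndarray) -> np.ndarray:
        x = s[:n]
        y = s[n:]
        R = x * x + y * y
        ang = omega - d * R
        radial = mu - R * (a - R * (b - c * R))
        return np.concatenate(
            [y * ang + x * radial + bW @ x, -x * ang + y * radial]
        )

    return rhs


def integrate(
    params: Sequence[CompartmentParams],
    A: Adjacency | np.ndarray,
    beta: float,
    config: SimulationConfig | None = None,
    state0: np.ndarray | None = None,
    coupling: str = "absolute",
) -> Trajectory:
    """Integrate the coupled system and sample it on a uniform grid.

    ``state0`` overrides the config's initial-state policy (and is required
    when that policy is "explicit").

    ``coupling`` selects how beta scales the adjacency: "absolute" applies
    the literal term beta*(A x); "degree-normalized" divides each row of A
    by its weighted degree first, so beta measures the total coupling input
    a node receives rather than the per-edge weight.  The normalised
    convention keeps the input scale comparable across network sizes and
    topologies and is what the packaged experiment presets use.
    """
    config = config or SimulationConfig()
    n = len(params)
    if state0 is None:
        state0 = initial_state(params, config)
    state0 = np.asarray(state0, dtype=float)
    if state0.size != 2 * n:
        raise ValueError(
            f"state has {state0.size} entries, expected {2 * n}"
        )
    if not np.all(np.isfinite(state0)):
        raise IntegrationError("initial state contains non-finite entries")
    times = np.arange(0.0, config.t_end + 0.5 * config.sample_dt, config.sample_dt)
    sol = solve_ivp(
        _rhs_factory(params, A, beta, coupling),
        (0.0, float(times[-1])),
        state0,
        method="RK45",
        t_eval=times,
        rtol=config.rel_tol,
        atol=config.abs_tol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.argmax(~np.all(np.isfinite(states), axis=1))
        raise IntegrationError(
            f"non-finite state at t={sol.t[bad]:.3f}"
        )
    return Trajectory(
        sol.t, states[:, :n], states[:, n:], beta, config,
        omega=float(max(p.omega for p in params)),
    )


def _distinct_maxima(
    values: np.ndarray, times: np.ndarray, cluster_tol: float = 1e-3
) -> np.ndarray:
    """Cluster the local maxima of a sampled signal into distinct levels.

    Maxima are refined by quadratic interpolation through the three
    bracketing samples, then greedily clustered with absolute tolerance
    ``cluster_tol``; cluster means are returned sorted ascending.
    """
    from .intermittency import extract_maxima  # local import, no cycle at runtime

    _, peaks = extract_maxima(values, times)
    if peaks.size == 0:
        return np.empty(0)
    peaks = np.sort(peaks)
    clusters: list[list[float]] = [[peaks[0]]]
    for v in peaks[1:]:
        if v - clusters[-1][-1] <= cluster_tol:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return np.array([float(np.mean(cl)) for cl in clusters])


def sweep_beta(
    params: Sequence[CompartmentParams],
    A: Adjacency | np.ndarray,
    beta_grid: np.ndarray,
    direction: str = "forward",
    config: SimulationConfig | None = None,
    observable: str = "x",
    compartment: int = 2,
    cluster_tol: float = 1e-3,
    coupling: str = "absolute",
) -> BifurcationDiagram:
    """Continuation sweep over beta recording distinct maxima of one signal.

    ``direction`` "forward" traverses ``beta_grid`` ascending, "backward"
    descending; either way each beta starts from the final state of the
    previous one so that the attractor is continued.  The observable
    defaults to x of the third compartment.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward/backward, got {direction!r}")
    config = config or SimulationConfig()
    grid = np.sort(np.asarray(beta_grid, dtype=float))
    if direction == "backward":
        grid = grid[::-1]
    state = initial_state(params, config) if config.initial_policy != "explicit" else None
    maxima: list[np.ndarray] = []
    failed: list[bool] = []
    for beta in grid:
        try:
            traj = integrate(
                params, A, float(beta), config, state0=state, coupling=coupling
            )
        except IntegrationError:
            maxima.append(np.empty(0))
            failed.append(True)
            continue
        state = traj.final_state()
        post = traj.after(config.t_transient)
        sig = post.x if observable == "x" else post.y
        if observable == "r":
            sig = post.r()
        maxima.append(
            _distinct_maxima(sig[:, compartment], post.times, cluster_tol)
        )
        failed.append(False)
    return BifurcationDiagram(
        grid, maxima, direction, observable, compartment, failed
    )


def is_locked(
    params: Sequence[CompartmentParams],
    A: Adjacency | np.ndarray,
    beta: float,
    config: SimulationConfig | None = None,
    r_threshold: float = 1.5,
    state0: np.ndarray | None = None,
    coupling: str = "absolute",
) -> bool:
    """Classify one beta as phase-locked (True) or intermittent (False).

    Integrates for the configured horizon and looks for genuine state
    switching: a compartment counts as intermittent only when it dwells on
    BOTH sides of ``r_threshold`` for at least one full fast rotation
    period within the post-transient window.  Sub-period threshold
    crossings of a single distorted orbit (the x-coupling makes locked
    orbits non-circular) are not switching and classify as locked, as does
    a network that never leaves either band.
    """
    config = config or SimulationConfig()
    traj = integrate(params, A, beta, config, state0=state0, coupling=coupling)
    post = traj.after(config.t_transient)
    r = post.r()
    t = post.times
    min_dwell = post.fast_period()
    for i in range(r.shape[1]):
        above = r[:, i] > r_threshold
        if _has_dwell(t, above, min_dwell) and _has_dwell(t, ~above, min_dwell):
            return False
    return True


def _has_dwell(t: np.ndarray, mask: np.ndarray, min_duration: float) -> bool:
    """True when some maximal run of ``mask`` lasts >= min_duration."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.view(np.int8))).reshape(-1, 2)
    for start, stop in edges:
        if t[min(stop, t.size - 1)] - t[start] >= min_duration:
            return True
    return False


def find_intermittency_onset(
    params: Sequence[CompartmentParams],
    A: Adjacency | np.ndarray,
    beta_bracket: tuple[float, float],
    config: SimulationConfig | None = None,
    resolution: float = 1e-3,
    r_threshold: float = 1.5,
    coupling: str = "absolute",
) -> float:
    """Bisect for the coupling strength at which locking first fails.

    ``beta_bracket`` must bracket the transition: the lower end classifies
    as intermittent and the upper as locked.  Returns the midpoint of the
    final bracket at the requested beta ``resolution``.
    """
    lo, hi = float(beta_bracket[0]), float(beta_bracket[1])
    if not lo < hi:
        raise ValueError(f"degenerate bracket ({lo}, {hi})")
    config = config or SimulationConfig()
    lo_locked = is_locked(params, A, lo, config, r_threshold, coupling=coupling)
    hi_locked = is_locked(params, A, hi, config, r_threshold, coupling=coupling)
    if lo_locked or not hi_locked:
        raise ValueError(
            f"bracket endpoints do not straddle the onset: "
            f"beta={lo} locked={lo_locked}, beta={hi} locked={hi_locked}; "
            "widen the bracket"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if is_locked(params, A, mid, config, r_threshold, coupling=coupling):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
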