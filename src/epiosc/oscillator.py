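"""Single-compartment oscillator model and the coupled vector field.

Each compartment is a planar oscillator written in polar form as

    r' = r (mu - a r^2 + b r^4 - c r^6),    theta' = omega - d r^2,

so that with R = r^2 the radial nullclines solve mu = F(R) where
F(R) = a R - b R^2 + c R^3 is a cubic amplitude curve.  For the default
coefficients (a=2, b=3/2, c=1/3) the curve has turning points at R=1 and
R=2, producing a Hopf bifurcation at mu=0 and a pair of saddle-node
bifurcations of periodic orbits at mu=5/6 and mu=2/3 that bracket a window
of bistability between a small- and a large-amplitude limit cycle.

Compartments are coupled additively through the x-coordinate only:

    x_i' = y_i (omega - d R_i) + x_i (mu_i - a R_i + b R_i^2 - c R_i^3)
           + beta (A x)_i
    y_i' = -x_i (omega - d R_i) + y_i (mu_i - a R_i + b R_i^2 - c R_i^3)

with A a symmetric, zero-diagonal adjacency matrix and beta a global
coupling strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "CompartmentParams",
    "BifurcationSet",
    "DegenerateCircleWarning",
    "amplitude_polynomial",
    "turning_points",
    "bifurcation_set",
    "limit_cycle_amplitudes",
    "equilibrium_stability",
    "angular_velocity",
    "coupled_vectorfield",
    "polar_vectorfield",
]

#: Tolerance below which two cubic roots are merged and flagged degenerate.
ROOT_MERGE_TOL = 1e-9


class DegenerateCircleWarning(UserWarning):
    """A periodic orbit lies on (or near) the circle r^2 = omega/d.

    On that circle the angular velocity vanishes, so the orbit degenerates
    into a ring of fixed points rather than a limit cycle.
    """


@dataclass(frozen=True)
class CompartmentParams:
    """Intrinsic parameters of one compartment.

    Parameters
    ----------
    mu : float
        Bifurcation parameter controlling oscillation amplitude; larger
        values place the compartment closer to (or past) the saddle-node
        that creates the large-amplitude rhythm, i.e. make it more
        "epileptogenic".
    a, b, c : float
        Strictly positive coefficients of the cubic amplitude curve
        F(R) = aR - bR^2 + cR^3.  Defaults a=2, b=3/2, c=1/3 give turning
        points at R=1 and R=2.
    omega : float
        Base angular velocity of the oscillation (radians per unit time).
    d : float
        Amplitude-frequency coupling; theta' = omega - d r^2, so d >= 0
        slows the oscillation as its amplitude grows.
    """

    mu: float = 0.0
    a: float = 2.0
    b: float = 1.5
    c: float = 1.0 / 3.0
    omega: float = 3.5
    d: float = 2.5

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(
                f"a, b, c must be strictly positive, got a={self.a}, "
                f"b={self.b}, c={self.c}"
            )
        if self.d < 0:
            raise ValueError(f"d must be non-negative, got d={self.d}")
        for name in ("mu", "omega"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def with_mu(self, mu: float) -> "CompartmentParams":
        """Copy of these parameters with a different ``mu``."""
        return replace(self, mu=float(mu))


@dataclass(frozen=True)
class BifurcationSet:
    """Analytic bifurcation structure of the uncoupled compartment.

    Attributes
    ----------
    hopf_mu : float
        mu at which the origin changes stability (always 0 for this model).
    sn_R : tuple of float
        Squared amplitudes of the turning points of F (ascending); empty
        when F is monotone.
    sn_mu : tuple of float
        F evaluated at ``sn_R`` — the saddle-node mu values.
    bistable_interval : tuple of float or None
        (min(sn_mu), max(sn_mu)) when two distinct turning points exist,
        else None.
    degenerate : bool
        True when the two turning points coincide (cusp).
    """

    hopf_mu: float
    sn_R: tuple[float, ...]
    sn_mu: tuple[float, ...]
    bistable_interval: tuple[float, float] | None
    degenerate: bool = False


def amplitude_polynomial(R, params: CompartmentParams | None = None):
    """Evaluate the amplitude curve F(R) = aR - bR^2 + cR^3.

    ``R`` is a squared amplitude (R = r^2) and must be non-negative.
    Accepts scalars or arrays.
    """
    params = params or CompartmentParams()
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R is a squared amplitude and must be >= 0")
    out = params.a * R - params.b * R**2 + params.c * R**3
    return out.item() if out.ndim == 0 else out


def _amplitude_slope(R, params: CompartmentParams):
    """F'(R) = a - 2bR + 3cR^2."""
    R = np.asarray(R, dtype=float)
    out = params.a - 2.0 * params.b * R + 3.0 * params.c * R**2
    return out.item() if out.ndim == 0 else out


def turning_points(
    params: CompartmentParams | None = None,
) -> tuple[tuple[float, ...], bool]:
    """Positive roots of F'(R) = 0, i.e. the saddle-node squared amplitudes.

    Returns ``(roots, degenerate)``: roots ascending (possibly empty) and a
    flag marking the cusp case of a double root.  With the defaults the
    quadratic factors as (R-1)(R-2), so the roots are exactly 1 and 2.
    """
    params = params or CompartmentParams()
    a, b, c = params.a, params.b, params.c
    disc = 4.0 * b * b - 12.0 * a * c
    if disc < 0:
        return (), False
    sq = np.sqrt(disc)
    roots = sorted(((2.0 * b - sq) / (6.0 * c), (2.0 * b + sq) / (6.0 * c)))
    if roots[1] - roots[0] < ROOT_MERGE_TOL:
        mid = 0.5 * (roots[0] + roots[1])
        return ((mid,) if mid > 0 else ()), mid > 0
    pos = tuple(r for r in roots if r > 0)
    return pos, False


def bifurcation_set(params: CompartmentParams | None = None) -> BifurcationSet:
    """Full analytic bifurcation set of the uncoupled compartment.

    The origin loses stability at mu=0 (Hopf; the radial linearisation at
    r=0 has eigenvalue mu).  Saddle-node bifurcations of periodic orbits sit
    at mu = F(R*) for each turning point R* of F, and when two exist they
    bound the bistability window.
    """
    params = params or CompartmentParams()
    sn_R, degenerate = turning_points(params)
    sn_mu = tuple(amplitude_polynomial(R, params) for R in sn_R)
    interval = None
    if len(sn_mu) == 2 and not degenerate:
        interval = (min(sn_mu), max(sn_mu))
    return BifurcationSet(
        hopf_mu=0.0,
        sn_R=sn_R,
        sn_mu=sn_mu,
        bistable_interval=interval,
        degenerate=degenerate,
    )


def limit_cycle_amplitudes(
    mu: float,
    params: CompartmentParams | None = None,
    stability_tol: float = 1e-12,
) -> list[tuple[float, str]]:
    """Squared amplitudes of all periodic orbits at the given ``mu``.

    Solves F(R) = mu for strictly positive R.  An orbit is stable iff
    F'(R) > 0: the radial equation is r' = r (mu - F(R)), so the amplitude
    relaxes back onto branches where F increases.  Roots with |F'(R)| at or
    below ``stability_tol`` are labelled "degenerate".

    Returns a list of ``(R, label)`` sorted by R; label is one of
    "stable", "unstable", "degenerate".  Also warns when an orbit sits on
    the circle r^2 = omega/d of vanishing angular velocity.
    """
    params = params or CompartmentParams()
    # roots of cR^3 - bR^2 + aR - mu = 0
    coeffs = [params.c, -params.b, params.a, -float(mu)]
    roots = np.roots(coeffs)
    # a numerically split double root appears as a conjugate pair with
    # imaginary part ~sqrt(eps); keep those as real
    real = roots[np.abs(roots.imag) < 1e-6].real
    real = np.sort(real[real > 0])
    # merge near-coincident roots (tangency); exact double roots split
    # by ~1e-8 under floating point, so merge well above that scale
    merge_tol = max(ROOT_MERGE_TOL, 1e-6)
    merged: list[float] = []
    for R in real:
        if merged and abs(R - merged[-1]) < merge_tol * max(1.0, R):
            merged[-1] = 0.5 * (merged[-1] + R)
        else:
            merged.append(float(R))
    out: list[tuple[float, str]] = []
    for R in merged:
        slope = _amplitude_slope(R, params)
        if abs(slope) <= max(stability_tol, 1e-5 * max(1.0, abs(R))):
            label = "degenerate"
        else:
            label = "stable" if slope > 0 else "unstable"
        _warn_if_degenerate_circle(R, params)
        out.append((R, label))
    return out


def equilibrium_stability(mu: float) -> str:
    """Stability of the origin: "stable" (mu<0), "unstable" (mu>0), "marginal"."""
    if mu < 0:
        return "stable"
    if mu > 0:
        return "unstable"
    return "marginal"


def _warn_if_degenerate_circle(
    R: float, params: CompartmentParams, tol: float = 1e-6
) -> None:
    if params.d > 0 and abs(R - params.omega / params.d) < tol * max(
        1.0, params.omega / params.d
    ):
        warnings.warn(
            f"periodic orbit at R={R:.6g} lies on the degenerate circle "
            f"r^2 = omega/d = {params.omega / params.d:.6g} where the angular "
            "velocity vanishes",
            DegenerateCircleWarning,
            stacklevel=3,
        )


def angular_velocity(R, params: CompartmentParams | None = None):
    """Angular velocity theta' = omega - dR at squared amplitude R.

    Warns (rather than errors) when R sits on the degenerate circle
    R = omega/d where the rotation stalls.
    """
    params = params or CompartmentParams()
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr < 0):
        raise ValueError("R is a squared amplitude and must be >= 0")
    if params.d > 0:
        for Ri in np.atleast_1d(R_arr):
            _warn_if_degenerate_circle(float(Ri), params)
    out = params.omega - params.d * R_arr
    return out.item() if out.ndim == 0 else out


def _check_adjacency(A: np.ndarray, n: int) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape != (n, n):
        raise ValueError(f"adjacency must be {n}x{n}, got {A.shape}")
    if np.any(np.diagonal(A) != 0):
        raise ValueError("adjacency must have zero diagonal (no self-coupling)")
    return A


def coupled_vectorfield(
    x: np.ndarray,
    y: np.ndarray,
    params: Sequence[CompartmentParams],
    A: np.ndarray,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the coupled Cartesian system.

    The additive coupling term beta*(A x) enters the x-equation only; the
    y-equation is the uncoupled rotation/relaxation.  ``A`` must be square
    with zero diagonal (self-coupling lives in the intrinsic terms).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or len(params) != n:
        raise ValueError(
            f"dimension mismatch: x has {n}, y has {y.size}, "
            f"params has {len(params)} entries"
        )
    A = _check_adjacency(A, n)
    mu = np.array([p.mu for p in params])
    a = np.array([p.a for p in params])
    b = np.array([p.b for p in params])
    c = np.array([p.c for p in params])
    omega = np.array([p.omega for p in params])
    d = np.array([p.d for p in params])
    R = x * x + y * y
    ang = omega - d * R
    radial = mu - a * R + b * R**2 - c * R**3
    dx = y * ang + x * radial + beta * (A @ x)
    dy = -x * ang + y * radial
    return dx, dy


def polar_vectorfield(
    r: float, params: CompartmentParams
) -> tuple[float, float]:
    """Uncoupled polar right-hand side ``(r', theta')`` at radius r."""
    R = r * r
    rdot = r * (params.mu - params.a * R + params.b * R**2 - params.c * R**3)
    return rdot, params.omega - params.d * R
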