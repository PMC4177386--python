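"""Connectivity schemes and heterogeneity (mu) maps.

Three adjacency constructions are provided: all-to-all, nearest-neighbour
on a 2-D periodic lattice, and exponentially distance-weighted coupling on
the same lattice.  Distances on a periodic lattice use the minimal-image
convention (shortest wrap-around Euclidean distance on the torus).

Two heterogeneity maps place an epileptogenic region at the lattice
centre: a uniform central square embedded in a normally distributed
background, and a radially decaying exponential profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LatticeSpec",
    "Adjacency",
    "MuField",
    "all_to_all",
    "nearest_neighbour",
    "distance_weighted",
    "mu_central_square",
    "mu_exponential_decay",
]


@dataclass(frozen=True)
class LatticeSpec:
    """A rectangular 2-D lattice of compartments.

    Nodes are indexed row-major; node i sits at position
    (i // n_cols, i % n_cols) in units of ``spacing``.  With
    ``periodic=True`` (the default) the sheet is a torus and distances use
    the minimal-image convention.
    """

    n_rows: int = 9
    n_cols: int = 9
    spacing: float = 1.0
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n(self) -> int:
        return self.n_rows * self.n_cols

    def positions(self) -> np.ndarray:
        """(N, 2) array of node coordinates, row-major order."""
        rows, cols = np.divmod(np.arange(self.n), self.n_cols)
        return self.spacing * np.column_stack([rows, cols]).astype(float)

    def pairwise_distances(self) -> np.ndarray:
        """(N, N) Euclidean distances, minimal-image if periodic."""
        p = self.positions()
        diff = np.abs(p[:, None, :] - p[None, :, :])
        if self.periodic:
            period = self.spacing * np.array([self.n_rows, self.n_cols])
            diff = np.minimum(diff, period - diff)
        return np.sqrt((diff**2).sum(axis=-1))

    def center_index(self) -> int:
        """Index of the central node (middle row/column; ties round down)."""
        return (self.n_rows // 2) * self.n_cols + self.n_cols // 2


@dataclass(frozen=True)
class Adjacency:
    """Symmetric, zero-diagonal, non-negative coupling weights."""

    weights: np.ndarray
    scheme: str = "custom"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.allclose(W, W.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diagonal(W) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(W < 0):
            raise ValueError("adjacency weights must be non-negative")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def save(self, path: str | Path) -> None:
        """Write weights as delimited text with a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.weights, delimiter="\t")
        meta = {"scheme": self.scheme, "n": self.n, **self.metadata}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "Adjacency":
        path = Path(path)
        W = np.loadtxt(path, delimiter="\t")
        side = path.with_suffix(path.suffix + ".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        scheme = meta.pop("scheme", "custom")
        meta.pop("n", None)
        return cls(W, scheme=scheme, metadata=meta)


@dataclass(frozen=True)
class MuField:
    """Per-node bifurcation-parameter values with generation metadata."""

    values: np.ndarray
    scheme: str = "custom"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("mu field must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("mu values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    def as_grid(self, lattice: LatticeSpec) -> np.ndarray:
        return self.values.reshape(lattice.n_rows, lattice.n_cols)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t")
        meta = {"scheme": self.scheme, "n": self.n, **self.metadata}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1)
        )


def all_to_all(n: int) -> Adjacency:
    """Fully connected network: every off-diagonal weight 1."""
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    W = np.ones((n, n)) - np.eye(n)
    return Adjacency(W, scheme="all-to-all", metadata={"n": n})


def nearest_neighbour(
    lattice: LatticeSpec, neighbourhood: str = "von-neumann"
) -> Adjacency:
    """Unweighted lattice-neighbour coupling on the (periodic) sheet.

    ``neighbourhood`` selects 4-connectivity ("von-neumann") or
    8-connectivity ("moore").
    """
    if neighbourhood not in ("von-neumann", "moore"):
        raise ValueError(f"unknown neighbourhood {neighbourhood!r}")
    dist = lattice.pairwise_distances()
    if neighbourhood == "von-neumann":
        W = (np.abs(dist - lattice.spacing) < 1e-12).astype(float)
    else:
        W = (
            (dist > 0) & (dist < lattice.spacing * np.sqrt(2) + 1e-12)
        ).astype(float)
    np.fill_diagonal(W, 0.0)
    return Adjacency(
        W,
        scheme=f"nearest-neighbour-{neighbourhood}",
        metadata={
            "n_rows": lattice.n_rows,
            "n_cols": lattice.n_cols,
            "periodic": lattice.periodic,
        },
    )


def distance_weighted(lattice: LatticeSpec, alpha: float) -> Adjacency:
    """Exponentially decaying coupling a_ij = exp(-alpha ||p_i - p_j||).

    Off-diagonal weights are normalised so the maximum entry is exactly 1
    (on a unit lattice the nearest-neighbour weight); the diagonal is
    forced to zero before normalisation so self-coupling never enters.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    dist = lattice.pairwise_distances()
    W = np.exp(-alpha * dist)
    np.fill_diagonal(W, 0.0)
    m = W.max()
    if m > 0:
        W = W / m
    # exact unity where distance equals the off-diagonal minimum
    off = dist[dist > 0]
    if off.size:
        W[np.abs(dist - off.min()) < 1e-12] = 1.0
    np.fill_diagonal(W, 0.0)
    return Adjacency(
        W,
        scheme="distance-weighted",
        metadata={
            "alpha": alpha,
            "n_rows": lattice.n_rows,
            "n_cols": lattice.n_cols,
            "periodic": lattice.periodic,
        },
    )


def _central_block_indices(
    lattice: LatticeSpec, side: int
) -> np.ndarray:
    r0 = (lattice.n_rows - side) // 2
    c0 = (lattice.n_cols - side) // 2
    rows = np.arange(r0, r0 + side)
    cols = np.arange(c0, c0 + side)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return (rr * lattice.n_cols + cc).ravel()


def mu_central_square(
    lattice: LatticeSpec,
    core_side: int = 3,
    core_mu: float = 0.6,
    bg_mean: float = 0.3,
    bg_variance: float = 0.05,
    seed: int | None = None,
) -> MuField:
    """Epileptogenic square embedded in a normally distributed background.

    The centred ``core_side`` x ``core_side`` block is set to ``core_mu``;
    every other node draws mu independently from
    Normal(bg_mean, bg_variance).  ``bg_variance`` is a variance, not a
    standard deviation, and no clipping is applied, so occasional negative
    background values are possible (and meaningful: such compartments sit
    below the Hopf bifurcation).
    """
    if core_side > min(lattice.n_rows, lattice.n_cols):
        raise ValueError("core does not fit inside the lattice")
    if bg_variance < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    values = bg_mean + np.sqrt(bg_variance) * rng.standard_normal(lattice.n)
    core = _central_block_indices(lattice, core_side)
    values[core] = core_mu
    return MuField(
        values,
        scheme="central-square",
        metadata={
            "core_side": core_side,
            "core_mu": core_mu,
            "bg_mean": bg_mean,
            "bg_variance": bg_variance,
            "seed": seed,
        },
    )


def mu_exponential_decay(
    lattice: LatticeSpec,
    center_mu: float = 0.6,
    asymptote_mu: float = 0.3,
    decay: float = 1.0,
) -> MuField:
    """Graded epileptogenic region decaying from the central node.

    mu_i = asymptote + (center - asymptote) * exp(-decay * d_i) with d_i
    the minimal-image distance from the central node, so the centre sits
    at ``center_mu`` exactly and the periphery approaches
    ``asymptote_mu``.
    """
    if decay <= 0:
        raise ValueError(f"decay must be > 0, got {decay}")
    dist = lattice.pairwise_distances()[lattice.center_index()]
    values = asymptote_mu + (center_mu - asymptote_mu) * np.exp(-decay * dist)
    return MuField(
        values,
        scheme="exponential-decay",
        metadata={
            "center_mu": center_mu,
            "asymptote_mu": asymptote_mu,
            "decay": decay,
        },
    )
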