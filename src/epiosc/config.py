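"""Experiment configuration, serialisation, and figure presets.

An :class:`ExperimentConfig` bundles everything needed to re-run an
experiment bit-identically: shared oscillator coefficients, per-node mu
values (explicit or generated from a lattice scheme), the connectivity
scheme, the coupling strength (or sweep grid), and the simulation
settings.  Configs round-trip through JSON; every defaulted field is
recorded so a saved snapshot is self-describing.

The figure presets encode the published parameter choices of the
experiments this model was introduced with; values the source never
printed (omega, d, the distance-decay rate alpha, horizons, seeds) are
package choices and are marked ``"assumed"`` in the preset metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .oscillator import CompartmentParams
from .networks import (
    Adjacency,
    LatticeSpec,
    MuField,
    all_to_all,
    distance_weighted,
    mu_central_square,
    mu_exponential_decay,
    nearest_neighbour,
)
from .simulate import SimulationConfig

__all__ = ["ExperimentConfig", "load_config", "save_config", "preset", "PRESET_NAMES"]

# Shared oscillator defaults.  a, b, c are the published amplitude-curve
# coefficients; omega and d were never printed for the original
# experiments and are package choices (see docs/methods.md).
DEFAULT_SHARED = {"a": 2.0, "b": 1.5, "c": 1.0 / 3.0, "omega": 3.5, "d": 2.5}

_KNOWN_KEYS = {
    "name",
    "coupling",
    "shared",
    "mu",
    "mu_scheme",
    "network",
    "beta",
    "beta_grid",
    "simulation",
    "analysis",
    "seed",
    "assumed",
    "notes",
}


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    ``mu`` is either an explicit list of per-compartment values or None
    with ``mu_scheme`` describing how to generate a field on the lattice.
    ``network`` holds the scheme name plus its parameters.  ``assumed``
    lists fields whose values the original experiments never specified.
    """

    name: str = "custom"
    shared: dict = field(default_factory=lambda: dict(DEFAULT_SHARED))
    mu: list | None = None
    mu_scheme: dict | None = None
    network: dict = field(default_factory=lambda: {"scheme": "all-to-all", "n": 3})
    beta: float | None = None
    beta_grid: list | None = None
    coupling: str = "absolute"
    simulation: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    seed: int = 0
    assumed: list = field(default_factory=list)
    notes: str = ""
    defaulted: list = field(default_factory=list, repr=False)

    # -- construction helpers -------------------------------------------------

    def lattice(self) -> LatticeSpec:
        net = self.network
        return LatticeSpec(
            n_rows=net.get("n_rows", 9),
            n_cols=net.get("n_cols", 9),
            spacing=net.get("spacing", 1.0),
            periodic=net.get("periodic", True),
        )

    def build_adjacency(self) -> Adjacency:
        scheme = self.network.get("scheme")
        if scheme == "all-to-all":
            return all_to_all(self.network.get("n", 3))
        if scheme == "nearest-neighbour":
            return nearest_neighbour(
                self.lattice(),
                self.network.get("neighbourhood", "von-neumann"),
            )
        if scheme == "distance-weighted":
            return distance_weighted(
                self.lattice(), self.network.get("alpha", 1.0)
            )
        raise ValueError(f"unknown connectivity scheme {scheme!r}")

    def build_mu(self) -> np.ndarray:
        if self.mu is not None:
            return np.asarray(self.mu, dtype=float)
        if self.mu_scheme is None:
            raise ValueError("config specifies neither mu nor mu_scheme")
        sch = dict(self.mu_scheme)
        kind = sch.pop("scheme")
        if kind == "central-square":
            sch.setdefault("seed", self.seed)
            return mu_central_square(self.lattice(), **sch).values
        if kind == "exponential-decay":
            return mu_exponential_decay(self.lattice(), **sch).values
        raise ValueError(f"unknown mu scheme {kind!r}")

    def build_params(self) -> list[CompartmentParams]:
        mu = self.build_mu()
        s = self.shared
        return [
            CompartmentParams(
                mu=float(m),
                a=s["a"],
                b=s["b"],
                c=s["c"],
                omega=s["omega"],
                d=s["d"],
            )
            for m in mu
        ]

    def build_simulation(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out.pop("defaulted", None)
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    cfg.save(path)


def _from_dict(data: dict) -> ExperimentConfig:
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    fields = {f.name for f in dataclasses.fields(ExperimentConfig)}
    kwargs = {k: v for k, v in data.items() if k in fields}
    cfg = ExperimentConfig(**kwargs)
    # record which shared coefficients were filled from defaults
    provided = set(data.get("shared", {}))
    merged = dict(DEFAULT_SHARED)
    merged.update(data.get("shared", {}))
    cfg.shared = merged
    cfg.defaulted = sorted(set(DEFAULT_SHARED) - provided)
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a JSON experiment config, filling defaults.

    Unknown keys raise with the offending name; defaulted shared
    coefficients are recorded on the returned object.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config must be a JSON object")
    return _from_dict(data)


# -- figure presets ----------------------------------------------------------

#: Package-chosen values for quantities the original experiments left
#: unstated; recorded as "assumed" in every preset.  The coupling
#: convention (beta as total input via degree normalisation) is likewise a
#: package choice: it is the scale on which the presets' printed beta
#: values reproduce the published regimes.
_ASSUMED = ["shared.omega", "shared.d", "coupling", "simulation", "seed"]


def _fig2_like(name: str, beta: float, t_end: float) -> ExperimentConfig:
    return ExperimentConfig(
        name=name,
        mu=[0.2, 0.3, 0.6],
        network={"scheme": "all-to-all", "n": 3},
        beta=beta,
        coupling="degree-normalized",
        simulation={"t_end": t_end, "t_transient": 100.0, "sample_dt": 0.05},
        assumed=list(_ASSUMED),
        notes="three all-to-all compartments, heterogeneous mu",
    )


def preset(name: str) -> ExperimentConfig:
    """Published experiment setups by figure name.

    fig2: three all-to-all compartments, mu=(0.2, 0.3, 0.6), beta=3/2 —
    the intermittency demonstration.  fig4: the same system swept over a
    beta grid in both directions.  fig5: the same system near the locking
    onset.  fig7: 9x9 nearest-neighbour torus with a central 3x3
    epileptogenic square (mu=0.6) in a Normal(0.3, 0.05) background,
    beta=2.75.  fig9: 9x9 distance-weighted torus with exponential mu
    decay from 0.6 to 0.3, beta=5.
    """
    if name == "fig2":
        return _fig2_like("fig2", beta=1.5, t_end=4000.0)
    if name == "fig4":
        cfg = _fig2_like("fig4", beta=1.5, t_end=400.0)
        cfg.beta = None
        cfg.beta_grid = [round(b, 3) for b in np.arange(1.5, 3.0001, 0.1)]
        cfg.simulation["t_transient"] = 150.0
        return cfg
    if name == "fig5":
        return _fig2_like("fig5", beta=1.897, t_end=4000.0)
    if name == "fig7":
        return ExperimentConfig(
            name="fig7",
            mu_scheme={
                "scheme": "central-square",
                "core_side": 3,
                "core_mu": 0.6,
                "bg_mean": 0.3,
                "bg_variance": 0.05,
            },
            network={
                "scheme": "nearest-neighbour",
                "n_rows": 9,
                "n_cols": 9,
                "neighbourhood": "von-neumann",
                "periodic": True,
            },
            beta=2.75,
            coupling="degree-normalized",
            simulation={"t_end": 1200.0, "t_transient": 100.0, "sample_dt": 0.05},
            assumed=list(_ASSUMED) + ["network.neighbourhood"],
            notes="central epileptogenic square in a normal background",
        )
    if name == "fig9":
        return ExperimentConfig(
            name="fig9",
            mu_scheme={
                "scheme": "exponential-decay",
                "center_mu": 0.6,
                "asymptote_mu": 0.3,
                "decay": 1.0,
            },
            network={
                "scheme": "distance-weighted",
                "n_rows": 9,
                "n_cols": 9,
                "alpha": 1.0,
                "periodic": True,
            },
            beta=5.0,
            coupling="degree-normalized",
            simulation={"t_end": 1200.0, "t_transient": 100.0, "sample_dt": 0.05},
            assumed=list(_ASSUMED) + ["network.alpha", "mu_scheme.decay"],
            notes="graded epileptogenic region with distance-dependent coupling",
        )
    raise ValueError(
        f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
    )


PRESET_NAMES = ("fig2", "fig4", "fig5", "fig7", "fig9")
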