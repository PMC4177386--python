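# epiosc

Coupled heterogeneous oscillator networks for studying intermittent,
seizure-like state transitions.

## The problem

In absence epilepsy, short epochs of high-amplitude slow spike-wave
rhythms arise spontaneously out of a low-amplitude background EEG and
stop again by themselves. One proposed dynamical explanation is
*type-1 intermittency*: the brain network sits just past a tangent
(saddle-node) bifurcation of a phase-locked rhythm, so trajectories
repeatedly crawl through the ghost of that rhythm (the seizure-like
"laminar" phase) and are re-injected into the background state.

`epiosc` implements a deliberately minimal model of this mechanism.
Each network node ("compartment", one patch of tissue) is a planar
oscillator,

    r' = r (μ − a r² + b r⁴ − c r⁶),     θ' = ω − d r²,

whose squared amplitude R = r² solves μ = F(R) with
F(R) = aR − bR² + cR³ on periodic orbits. With the fixed coefficients
a = 2, b = 3/2, c = 1/3, the compartment has a Hopf bifurcation at μ = 0
and saddle-node bifurcations of periodic orbits at μ = 2/3 (R = 2) and
μ = 5/6 (R = 1), giving a bistability window μ ∈ (2/3, 5/6) between a
small-amplitude (background) and a large-amplitude, slower (seizure-like)
rhythm. A compartment's μ measures its epileptogenicity. Compartments
are coupled additively through the x-coordinate, β(Ax)ᵢ, over all-to-all,
lattice nearest-neighbour, or exponentially distance-weighted networks.

The package provides the analytic bifurcation set, the coupled-network
simulator, β-sweep continuation with forward/backward hysteresis, and the
intermittency toolbox (first-return maps, tangency gaps, laminar-phase
segmentation, duration histograms).

## Worked example

The canonical three-compartment experiment: heterogeneous excitability
μ = (0.2, 0.3, 0.6), all-to-all coupling, β = 3/2.

```python
import numpy as np
from epiosc import preset, integrate, segment_laminar, bifurcation_set

bs = bifurcation_set()
print("saddle-node mu values:", bs.sn_mu)

cfg = preset("fig2")
traj = integrate(cfg.build_params(), cfg.build_adjacency(), cfg.beta,
                 cfg.build_simulation(), coupling=cfg.coupling)
post = traj.after(100.0)
phases = segment_laminar(post, compartment=2)
print("compartment-3 laminar episodes:", phases.n_episodes)
print("median duration:", round(float(np.median(phases.durations)), 1))
```

prints

```
saddle-node mu values: (0.8333333333333333, 0.6666666666666665)
compartment-3 laminar episodes: 28
median duration: 2.0
```

The saddle-node μ values 5/6 and 2/3 bound the single-compartment
bistability window. Although every compartment sits *below* the
saddle-node at 2/3 (none can sustain the high-amplitude rhythm alone),
the coupled network drives compartment 3 into 28 transient high-amplitude
(r > 1.5) episodes over the run — the intermittent, seizure-like
switching the model exists to reproduce. Increasing β past the locking
onset (≈ 1.74 for the packaged parameter choice; locate it with
`find_intermittency_onset`) replaces the switching with a permanently
phase-locked rhythm, and sweeping β back and forth
(`sweep_beta(..., "forward"/"backward")`) shows the locked and
intermittent branches with hysteresis.

The same machinery runs from the command line:

```
epiosc bifurcation
epiosc simulate --preset fig2 --out runs/fig2
epiosc analyze runs/fig2/trajectory.tsv --compartment 2 --observable y
epiosc sweep --preset fig4 --out runs/fig4
```

## Layout

* `epiosc.oscillator` — single-compartment analytics and the coupled
  vector field
* `epiosc.networks` — adjacency builders (all-to-all, lattice
  nearest-neighbour, distance-weighted) and epileptogenicity maps
* `epiosc.simulate` — integration, β sweeps, onset bisection
* `epiosc.intermittency` — return maps, laminar segmentation, duration
  statistics
* `epiosc.config` / `epiosc.cli` — experiment configs, figure presets,
  command-line interface

See `docs/methods.md` for the model assumptions, parameter choices and
their rationale, and known limitations.
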