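# Methods

## The model

Each network node ("compartment") stands for a patch of cortical tissue
whose population activity oscillates. The compartment is a planar
oscillator written in polar coordinates as

    r' = r (mu - a r^2 + b r^4 - c r^6)
    theta' = omega - d r^2

With R = r^2, periodic orbits solve mu = F(R) where F(R) = aR - bR^2 +
cR^3. The coefficients a=2, b=3/2, c=1/3 are fixed throughout; they place
the turning points of F at R=1 and R=2, so the uncoupled compartment has

* a Hopf bifurcation at mu = 0 creating a stable small-amplitude cycle,
* a saddle-node of periodic orbits at mu = 2/3 (R = 2) creating a stable
  large-amplitude cycle together with an unstable one,
* a second saddle-node at mu = 5/6 (R = 1) destroying the small cycle,

hence a bistability window mu in (2/3, 5/6) between qualitatively
different rhythms. The large-amplitude, slower rhythm is identified with
seizure-like activity; mu measures how excitable ("epileptogenic") a
compartment is — how close it sits to the saddle-node at 2/3.

Compartments are coupled additively through the x-coordinate only:

    x_i' = y_i (omega - d R_i) + x_i (mu_i - a R_i + b R_i^2 - c R_i^3) + beta (A x)_i
    y_i' = -x_i (omega - d R_i) + y_i (mu_i - a R_i + b R_i^2 - c R_i^3)

A is symmetric with zero diagonal (self-coupling is part of the intrinsic
terms). All compartments in the canonical experiments sit below the
saddle-node at 2/3, so no compartment can sustain the high-amplitude
rhythm alone; transient, repeated excursions into it are a genuine
network effect.

## Coupling conventions

`coupled_vectorfield` and the simulator implement the literal term
beta*(A x) ("absolute" convention). The simulator additionally offers a
"degree-normalized" convention in which each row of A is divided by its
weighted degree, so beta measures the *total* coupling input a node
receives rather than the per-edge weight. The packaged experiment presets
use the normalised convention: it keeps the input scale comparable across
network sizes and topologies (a standard practice for neural mass
networks), and it is the scale on which a single set of oscillator
parameters reproduces the canonical regimes — intermittent bursting at
beta = 3/2 in the three-compartment system, locking onset near beta = 1.7,
and the lattice experiments at beta = 2.75 and beta = 5 — with one
consistent parameterisation. With the absolute convention those regimes
sit at beta values roughly one weighted-degree lower.

## Choice of omega and d

The rotation rate omega and the amplitude–frequency coupling d are free
parameters of the abstraction (the bifurcation structure in r is
independent of them) and strongly shape the coupled dynamics. The package
defaults, used by all presets, are omega = 3.5 and d = 2.5. They were
selected by a systematic scan of the (omega, d) plane with two
requirements:

1. **A protected low state.** The x-only coupling resonantly pumps a
   compartment whose rotation matches its neighbours'. With substantial
   d, a driven compartment detunes itself as its amplitude grows
   (theta' = omega - dR falls), so the response saturates below the
   escape barrier — background compartments can then coexist with
   high-amplitude neighbours instead of being dragged up. Without this
   (small d, or any omega at d = 0), the fully synchronous high-amplitude
   state captures the whole network for all beta of interest and no
   intermittent regime exists at the canonical coupling strengths.

2. **Frequency separation of the two rhythms.** At omega = 3.5,
   d = 2.5 the small cycle rotates near omega while the large-amplitude
   state rotates in the opposite sense (theta' changes sign at
   R = omega/d = 1.4, between the two uncoupled bands); the high-amplitude
   rhythm is therefore strongly off-resonant from the background, which
   is what terminates each burst and re-injects the compartment into the
   low state.

The degenerate circle r^2 = omega/d carries zero angular velocity; with
the defaults it lies at R = 1.4, inside the unstable gap between the two
attracting bands, which the analytic routines flag (warning, not error)
if an orbit lands on it.

## Simulation and analysis choices

* Integration: adaptive RK45 (`scipy.integrate.solve_ivp`), rel_tol 1e-8,
  abs_tol 1e-10, sampled on a uniform grid (default dt = 0.05, about 36
  samples per fast period at omega = 3.5). The dynamics in the intermittent
  window is chaotic, so individual long trajectories are
  tolerance-sensitive; all qualitative analyses (episode counts, regime
  classification) are performed at the tolerances above, where the
  regime boundaries are stable.
* Initial conditions: each compartment starts on its uncoupled stable
  small-amplitude cycle at a seeded random phase ("on-small-cycles"
  policy). Explicit state override is available.
* Locking classifier: a run is "intermittent" when some compartment
  dwells on *both* sides of the laminar threshold for at least one full
  fast rotation period; sub-period threshold crossings of a single
  distorted orbit (the x-coupling makes locked orbits non-circular) do
  not count as switching. The intermittency onset is located by bisection
  of this classifier (default resolution 1e-3 in beta).
* Laminar segmentation: episodes are maximal intervals with
  r > 1.5 (midpoint of the saddle-node radii r = 1 and r = 2), with
  linear interpolation of crossing times and a minimum duration of one
  fast period 2*pi/omega to suppress threshold-grazing artefacts.
* Distinct maxima (sweep diagrams): local maxima refined by quadratic
  interpolation through the three bracketing samples, then clustered with
  absolute tolerance 1e-3.
* Return maps use successive local maxima of the chosen observable
  (Poincaré-section alternatives were considered and rejected for the
  default because maxima are what the sweep diagrams use).
* U-shape test: end bins of an equal-width histogram must strictly exceed
  every interior bin; with fewer than 20 durations only the histogram is
  returned. This is deliberately a simple criterion, not a formal dip
  test.

## What the presets reproduce, and what they do not

The presets encode the canonical experiments: three all-to-all
compartments with mu = (0.2, 0.3, 0.6) at beta = 3/2 (bursting), the same
system swept over beta in [1.5, 3] in both directions (locked regime at
high beta, intermittent regime at low beta, hysteresis between sweep
directions), a long run near the locking onset (first-return-map channel
and laminar-duration statistics), and two 9x9 periodic-lattice
experiments: a central 3x3 epileptogenic square (mu = 0.6) in a
Normal(0.3, 0.05) background with von Neumann coupling at beta = 2.75,
and a graded exponential mu-profile with distance-dependent coupling
(alpha = 1 per lattice unit) at beta = 5.

Because omega, d, the coupling convention, initial conditions, horizons
and seeds are package choices, agreement with the canonical experiments
is qualitative: the regime sequence over beta, the existence and
character of the intermittent window, and the spatial organisation of
lattice episodes — not specific trajectories or exact onset values.
Near the locking onset the system shows the type-1 signatures (a
near-tangent channel along the diagonal of the first-return map of
successive maxima, and long laminar phases whose mean length grows as
the onset is approached); the detailed shape of the laminar-duration
histogram depends on the re-injection mechanism and is not asserted
beyond what the tests compute.

## Limitations

* The model is an abstraction: no EEG waveform morphology (spike-wave
  shape), no noise-driven switching, no critical-slowing indicators.
* Episode statistics in the intermittent window are chaotic and
  tolerance- and seed-sensitive at the level of individual episodes;
  only regime-level statements are stable.
* Near the locking onset the re-injection in this parameterisation is
  rhythmic rather than broadly chaotic: laminar episode durations are
  capped at a few fast periods, so the laminar-duration histogram is
  short-end-heavy rather than U-shaped except at isolated coupling
  values.
* In the lattice experiments every node receives the same total coupling
  input, which is above the three-compartment locking threshold; the
  epileptogenic core is therefore largely captured by the high-amplitude
  state and its corner compartments (bordering quieter background nodes)
  switch more often, not less, than the core interior.
* The lattice experiments use scaled-down horizons; spatial episode
  statistics at much longer horizons were not characterised.
* No Floquet analysis of the coupled phase-locked orbit; tangency is
  detected empirically from return maps.
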