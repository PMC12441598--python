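# Methods

## Model overview

The population of Π slugs lives on two planar layers of a square field of
side L: the surface (z = 0) and a single effective depth underground.
Both layers are simulated in two dimensions; vertical movement is
instantaneous relocation between them, with the planar position kept.
Time is discrete; one tick represents Δt\* = 30 min, the interval at
which the movement distributions were parametrised from field releases.

Each tick executes, in order:

1. every surface slug is independently marked to burrow with probability
   p_d, and every buried slug to surface with probability p_u — both
   markings against the pre-tick memberships, so a slug cannot bounce
   within one tick;
2. marked slugs swap layers;
3. every slug in the *new* surface population takes a density-dependent
   horizontal step;
4. every slug in the new underground population takes a Brownian step.

No births or deaths occur (outside an explicit pesticide cull), so
N_t + P_t = Π at every tick; the simulator asserts this.

### Surface movement

A surface slug perceives the density D_l of other surface slugs within
its perception radius R: D_l = (neighbours within R)/(πR²).  The focal
slug is excluded.  The circle area is *not* truncated at the field
boundary, which biases D_l low for slugs within R of an edge (at the
default R = 1 m and L = 10 m, roughly a third of the area hosts some
bias; the mean perceived density of a uniform population is ≈ 6% below
the nominal value).  This is the simplest consistent estimator; an
edge-corrected variant would change regime assignments only in the
boundary strip.

The regime is **sparse** when D_l < d and **dense** when D_l ≥ d (the
threshold itself counts as dense).  The regime selects all three step
ingredients:

| parameter | meaning | sparse | dense | underground |
|---|---|---|---|---|
| p_m | movement frequency per tick | 0.5 | 0.25 | 1 (always moves) |
| turning angle | relative to previous heading | Von Mises(μ=0, κ=0.8) | uniform on circle | uniform on circle |
| step length | half-normal scale σ (m per tick) | 0.105 | 0.113 | 0.05 |

The sparse/dense frequencies, angle concentrations and step scales are
the values estimated from release experiments with *D. reticulatum*;
the density threshold d = 50 slugs m⁻² and R = 1 m sit mid-range of the
field estimates.  The underground scale has never been measured; 0.05 m
is a deliberate "slower than the surface" placeholder, and conclusions
that depend on underground mobility should be read with that in mind.
The dense-regime angle distribution is implemented as the exact uniform
law rather than a Von Mises with tiny κ, since it is the κ → 0 limit.

Turning is applied to a persistent per-slug heading.  The initial
heading is drawn uniformly on the circle (the movement rules define only
angle *changes*), and the heading is retained unchanged through rest
ticks and vertical transitions — the simplest stateful interpretation.
A resting slug re-evaluates its regime from the current density at every
tick.

### Boundary handling

The movement rules say nothing about the domain edge, so the boundary
rule is a configuration choice.  The default is specular **reflection**
(the overshoot is folded back and the heading mirrored in the wall),
which keeps the whole population inside the field and thus preserves the
conservation law that the analytic model assumes.  **Periodic** wrapping
is available via `SimulationConfig(boundary="periodic")` for users who
prefer a homogeneous torus.  Step lengths (≈ 0.1 m) are tiny relative to
L = 10 m, so the two rules differ only in a thin boundary layer.

### Initial condition

Coordinates are i.i.d. uniform on [0, L]² in both layers;
round(α Π) slugs start on the surface (default α = β = 1/2).

## Two-compartment model

Replacing the random exchanges by their expectations gives the linear
recurrence N_{t+1} = (1−p_d) N_t + p_u P_t (and its mirror for P).  The
imbalance W_t = p_d N_t − p_u P_t contracts geometrically,
W_{t+1} = C W_t with C = 1 − p_d − p_u, so the steady state
N\* = Π p_u/(p_u+p_d) is globally stable for p_u, p_d ∈ (0,1):
monotonically approached for 0 < C < 1, with alternating sign for
−1 < C < 0, and in a single step in the degenerate case C = 0.  All
compartment quantities are kept as continuous expectations; rounding to
whole slugs happens only in the IBM and in reports.

**Transition time.**  t\* is defined here as the last step at which
|W_t| still exceeds the tolerance ε, i.e. the largest integer strictly
below the real solution s of |W₀| |C|^s = ε (for non-integer s this is
simply ⌊s⌋); convergence is deemed reached at the first step where
|W_t| ≤ ε.  W₀ = 0 returns t\* = 0.  Because probabilities entered as
decimals can leave ~10⁻¹⁷ residue in C, |C| < 10⁻⁹ is treated as the
degenerate single-step case; the generic logarithm formula would
otherwise report t\* = 0 for p_u + p_d = 1, which is one step short.
The default ε = 10⁻⁴ (with Π = 10⁴) asks for the imbalance to fall
below 10⁻⁸ of the population — far below stochastic fluctuations, so
t\* is a conservative analytic bound.

**Flux and ratio.**  At equilibrium each direction carries
N_f = Π p_u p_d/(p_u+p_d) slugs per tick (scaled fraction f = N_f/Π),
and the layer ratio is r = N\*/P\* = p_u/p_d.  N_f/N\* = p_d is the
per-tick turnover of the surface population — the quantity that decides
whether surface patches survive vertical mixing.

## Spatial statistics

Snapshots are binned into an m × m grid (default m = 10, so M = 100
bins of 1 m² on the default domain).  Bins are half-open
[k L/m, (k+1) L/m) with the top edge closed, row-major in x.  The
cross-layer correlation is the Pearson coefficient over the M paired bin
densities; a zero-variance grid raises `ZeroVarianceError` rather than
returning 0, since a silent default would corrupt replicate averages
(the experiment runner excludes such replicates with a warning).
Replicate averaging uses NR = 5 by default; NR = 3 already smooths most
run-to-run oscillation.

## Pesticide algebra

Culling the equilibrium (N\*, P\*) with surviving fractions
(ω_o, ω_u) gives Ñ = ω_o N\*, P̃ = ω_u P\*, a reduced total
Π₁ = Ñ + P̃, and — because the transition probabilities are unchanged —
a new equilibrium that is just the steady-state formula applied to Π₁.
The actual efficiency e_a = 100(N\* − Ñ)/N\* and apparent efficiency
e_f = 100(N\* − N₁\*)/N\* then satisfy e_a ≥ e_f whenever ω_o < ω_u:
the underground reservoir refills the surface, and a count taken after
re-equilibration (hours, given t\* ≲ 10² ticks) understates the kill.
For a uniform cull (ω_o = ω_u = ω) both equal 100(1 − ω).  The
individual-level counterpart draws independent Bernoulli survival per
slug; an optional spatial mask restricts treatment to part of the field
(an extension for exploring patch-targeted application — the aggregate
algebra assumes a uniform cull).  ω_o ≥ ω_u is allowed but warns, since
molluscicides act mostly on the surface.

## Synthetic data and what the tests show

There are no external data: the IBM itself is the data generator, run at
the study conditions (L = 10 m, Π = 10⁴, Δt = 30 min, the movement
parameters above).  It reproduces the mechanisms under test —
density-dependent patch formation, vertical mixing, equilibration — but
not features of real fields such as soil heterogeneity, weather-driven
time variation of p_u and p_d, diurnal cycles, or reproduction.  Tests
passing here validate the implementation and the internal consistency of
the theory, not the ecological calibration of the underground and
vertical-movement parameters, which remain unmeasured.

Problem sizes used by the heavier consistency checks: IBM-versus-analytic
equilibrium at Π = 10⁴, T = 500 with 3 replicates per probability pair
(valid because t\* ≤ 82 ≪ 500), and the correlation-structure check at
Π = 10⁴, T = 2 000, NR = 3 — past the ~10³-tick patch-formation
timescale, while the published full-scale runs use T = 10⁴.  Sampler
moment checks run at n = 10⁵ with 3-standard-error bands.

## Numerical choices

* Exchange probabilities are implemented as `u < p` with u ~ U(0,1), so
  p = 0 and p = 1 behave exactly.
* Angles are wrapped to (−π, π]; any fixed convention would do, but one
  must be fixed for bit-reproducibility.
* One `numpy` Generator per run, seeded from the configuration;
  replicate k of an experiment uses seed + k.  Identical configurations
  are bit-reproducible.
* Neighbour counting uses a cell-list kernel (cells no smaller than R,
  3 × 3 neighbourhood scan) compiled with numba when available, with a
  `scipy.spatial.cKDTree` fallback producing identical counts.
* Reference tables are rounded to their printed precision (transition
  times to integers, ratio/flux to 3 decimals).

## Known limitations

* Constant p_u, p_d: no diurnal or weather-driven time dependence.
* No reproduction or natural mortality; the conservation law is exact.
* The underground step scale is hypothetical (see above).
* Local density is not edge-corrected (see above).
* The compartment model describes expectations only; for small
  populations the binomial fluctuations around N\* (standard deviation
  √(Π p̂(1−p̂)), p̂ = p_u/(p_u+p_d)) dominate the picture.
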