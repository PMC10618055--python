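# Model and methods

`foragersim` simulates the residential mobility, demography and cultural
evolution of hunter-gatherer camps on a time-dependent habitat-suitability
landscape. This note documents the model as implemented, the parameter
choices and their rationale, what the synthetic landscapes do and do not
emulate, and the numerical conventions a user needs to interpret results.

## State

An agent is a camp with a planar position `X_a(t)` (km), a real-valued
population `D_a(t)` (people), and an integer status vector `S_a(t)` of `c`
cultural features. The system state is the collection of all live camps.
The internal clock counts months since the start of the run; a fixed
mapping (`TimeMap`) converts it to years BP, which decrease as the
simulation advances.

## Mobility

Camp positions follow the SDE

    dX_a = -grad( V(X_a, t) + U_a(X) ) dt + sigma(X_a) dB_a

integrated by Euler-Maruyama at `dt` = 1 month.

* **Environmental potential.** `V(x, t) = -w_env * s(x, t)` where `s` is
  the bilinear interpolation of the active suitability slice (0 outside
  the domain). The negative linear map is the simplest monotone choice
  that makes attractive areas minima of the potential; `w_env` (default 1)
  rescales it. The gradient is taken by central differences with step
  `cell_size / 2` on the interpolant, which keeps `V` pluggable — the test
  suite injects a quadratic potential to check the integrator against the
  Ornstein-Uhlenbeck stationary law.
* **Interaction forces.** Camps interact through a Morse-like pair
  potential `W(d) = a_rep exp(-d/l_rep) - a_att exp(-d/l_att)`, truncated
  at the long-range radius (50 km): a repulsive core keeps foraging areas
  from overlapping, a weak attractive tail penalizes isolation. With the
  defaults (`a_rep = a_att = 5`, `l_rep = 5`, `l_att = 25`) the pair force
  vanishes at ~10 km, the nominal minimum spacing. Pair forces are capped
  at `f_max` = 2 km/month; coincident camps (fresh fission twins) separate
  along a deterministic pseudo-random direction hashed from the id pair,
  so runs are reproducible. Forces are evaluated as a vectorised all-pairs
  sum restricted to pairs within the cutoff; at the model's camp counts
  (tens to a few hundred) this is faster and simpler than a cell-list
  neighbour search and bit-identical to the brute-force sum.
* **Noise and barriers.** `sigma(x) = sigma0 * (1 - friction(x))`,
  floored at `barrier_sigma_floor * sigma0` in passable terrain and
  exactly 0 where friction = 1. `sigma0` = 0.4 km month^-1/2. Proposed
  steps into impassable cells (friction 1, or outside the domain) are
  rejected and the camp stays in place for that month — the simplest rule
  that guarantees barriers are never crossed; an exception lets a camp
  whose own cell has become impassable (landscape change) escape.
* **Moves.** A step displacement of at least 2 km counts as one
  residential move. Moves per agent-year, mean km per move and total km
  per year are computed with camps weighted by their alive time.

## Demography

The local carrying capacity `K_t(x)` is `kappa` times the suitability
integrated over the foraging disc of radius `r_f` = 20 km. The local
population seen by a camp is its own size plus neighbours' sizes weighted
by the exact circle-lens overlap fraction of their foraging discs (zero
from 2 `r_f` outward). While local population < K the camp grows as
`exp(rho_g dt)`, otherwise it declines as `exp(-rho_d dt)`
(`rho_g = rho_d = 0.001`/month; the tie goes to decline). Camps above the
fission threshold (60) split into two equal halves at the same position
and status (the parent keeps its id — a logging convention); camps below
the fusion threshold (18) merge into the nearest camp within 50 km,
smallest-first with id tie-breaks, or go extinct when none is in reach.
Fission and fusion conserve people exactly (per-operation, to float
rounding); only extinction removes them.

**Calibration of `kappa`.** `kappa` converts integrated suitability to
people and has no published value. It is the one constant we calibrated:
at `kappa = 0.25` people per km^2 of fully suitable land — mid-range of
ethnographic density estimates for Central African foragers — a fully
suitable foraging disc supports ~315 people (about five camps at the
fission threshold), and desk-scale systems sustain a persistent
fission-fusion population. Substantially smaller values leave single
camps above capacity once foraging-disc overlaps are counted, and the
system collapses; the value was fixed once on that viability argument,
not tuned to any downstream statistic.

## Cultural dynamics

The interaction network assigns weight `phi1` to pairs within
`r1` = 20 km, `phi2` to pairs within (r1, r2] = (20, 50] km (both bounds
inclusive), 0 otherwise. On this network a continuous-time Markov jump
process runs, simulated exactly with the Gillespie algorithm inside each
monthly step (operator splitting: network and positions frozen for the
month, rates rebuilt after every executed event; with all rates well
below 1/month the splitting error is negligible).

* **Progressive features** (technology-like): trait values count
  accumulated variants, floor 0, no ceiling. Innovation at rate `gamma`
  (+1), loss at rate `lam` (-1, suppressed at the floor), and adoption
  from a neighbour at rate `A_ab * max(S_b - S_a, 0)` — linear in the
  trait difference, the minimal monotone kernel under the "each variant
  independently learnable" reading; an adoption increments by exactly 1.
  The kernel is pluggable in `event_rate_catalogue`/`gillespie_window`
  should an indicator variant be wanted.
* **Non-progressive features** (song/ornament-like): unordered values in
  {0..Q-1} (default Q = 16; the number is only required to be finite, and
  results are insensitive to it at desk scale). Spontaneous switching to
  a uniformly drawn *different* value at rate `gamma`, and neutral
  copying of a neighbour's exact value at rate `A_ab` per differing
  feature.
* **Fusion coupling:** in progressive mode the absorbing camp takes the
  per-feature maximum of both status vectors — a merged camp instantly
  knows every variant either camp knew.

Rates are per month; the published ranges define the sweep grid, with
(phi1, phi2) = (0.02, 0.002) / (0.05, 0.005) / (0.1, 0.01) as the low /
medium / high adoption conditions.

## Observables

* **Simpson diversity**: one minus the probability that two camps drawn
  with replacement share the *same full status vector* (the stricter
  joint reading; a per-feature variant sits behind a flag). Camps weight
  equally.
* **Mean complexity**: plain across-camp mean per progressive feature.
* **Population-complexity correlation**: Pearson r of camp count against
  feature-averaged complexity across sampled time points (default
  sampling stride 120 months at desk scale).

## Clustering

* **Mobility clusters**: all sampled positions within one
  static-landscape window are pooled and clustered with HDBSCAN
  (scikit-learn). `min_cluster_size` defaults to five agents' worth of
  pooled points. Two post-passes give the hierarchy an absolute spatial
  scale: clusters separated by less than `cluster_selection_epsilon`
  (default 20 km — substructure at the repulsion-imposed camp spacing is
  not fragmentation) are single-linkage merged, and clusters with no
  density at that scale (median 5-NN distance above epsilon) are demoted
  to noise. Each agent takes the majority label of its own points.
* **Cultural clusters**: camps are close in status if identical
  (non-progressive) or within Euclidean distance `epsilon` = 2
  (progressive). The time-averaged closeness fraction over co-alive
  sampled steps forms a connectivity matrix `C`; its connected components
  above `theta` = 0.5 are the cultural clusters. Both knobs are config
  parameters; the defaults are round mid-range values, not fitted.
* **Cell maps and overlap**: each landscape cell takes the cultural
  cluster that most frequently occupied it (ties to the lowest label);
  mobility-vs-cultural labelings are cross-tabulated into the table
  behind an alluvial diagram.

## The monthly loop

Fixed substep order: landscape-slice refresh (carrying-capacity grid
recomputed only at slice boundaries) -> Euler-Maruyama move (+ move log)
-> network rebuild at post-move positions -> Gillespie window ->
demographic update -> fission -> fusion/extinction. The order is a
convention: cultural exchange uses post-move positions, fission/fusion
act on post-growth populations. Changing it is an API-visible change.

Runs are deterministic given (config, seed): initialization, mobility
noise and cultural events consume three independent generator streams
spawned from the seed, so ablating one subsystem leaves the others'
randomness untouched. The full system state (including generator states)
round-trips through a JSON checkpoint bit-exactly. Demographic events are
stamped at the end of their month (after the cultural window they
follow), which makes the combined event log replayable: applying cultural
and demographic events in time order to the initial statuses reproduces
the final cultural state exactly, and the suite checks this.

## Synthetic landscapes

The generator produces smooth patchy suitability fields (Gaussian random
fields squashed through a logistic), piecewise constant in time.
Successive slices share an AR(1) latent field (default coefficient 0.7)
and an AR(1) landscape-wide richness offset (default sd 0.5 logit
units): boundaries still carry abrupt changes, but the landscape
reorganizes gradually and passes through richer and poorer epochs, as
climate-projected suitability series do — with independent redraws every
boundary is a catastrophic reshuffle and the population never reaches a
statistical steady state across epochs. A ``mean_logit`` offset selects
between a rich connected regime (0) and sparse habitat islands
(negative). Optional impassable barrier strips (friction 1, suitability
0) can include corridor gaps. A second generator builds controlled
Gaussian-patch landscapes for fragmentation and isolation experiments.
These surrogates emulate the *statistical* features that drive the model
— bounded patchy suitability, abrupt temporal change, barriers — but not
the geography, autocorrelated climate trajectories, or empirical
suitability-occupancy calibration of a real niche-model stack. Passing
tests on them demonstrates the mechanisms (density-dependent demography,
mobility-mediated cultural connectivity, isolation-driven loss), not
quantitative history; full-size raster stacks can be supplied in ESRI
ASCII format with a CSV time index for real-landscape runs.

## Study conditions at desk scale

Reduced-scale defaults used by the experiment drivers and the acceptance
script: 100 x 100 grid of 5 km cells (500 x 500 km), 8 landscape epochs
of 250 years, 150 starting camps, a 500-year burn-in on the frozen
initial landscape (so the measured window starts from a demographically
and culturally equilibrated state with existing diversity, per the
initialization procedure), then 2 000 simulated years (24 000 monthly
steps), progressive mode with c = 3 features, 5 seeds per condition. The
isolation experiment uses an archipelago of small patches ~40 km apart
whose stepping-stone bridge is removed at a slice change: camps contract
to patch cores, so only the bridge chain carries culture across the
>50 km gap, and cutting it isolates the remote community — the model's
own mechanism for environmentally driven isolation. These sizes are the
package's chosen desk-scale study conditions; the engine itself is
indifferent to them.

## Numerical conventions and degenerate inputs

* Populations are reals; thresholds compare as reals, no rounding.
* `L = K` exactly takes the decline branch ("grows while below").
* Fission children: parent keeps its id; the twin gets a fresh id.
* Fusion partner: nearest; ties by lower id; starving camps processed
  smallest-population-first so cascades are deterministic.
* Zero agents terminates a run with an `extinct` flag, not an error.
* Suitability values outside [0, 1], gapped or overlapping time indexes,
  and shape-mismatched rasters are rejected at load time.
* An all-zero landscape cannot be sampled for initial positions and
  raises.
* Diversity/complexity are undefined (raise) for zero agents, as are
  mobility statistics for a move-free log.

## Known limitations

* **Population-complexity correlation at desk scale.** With the default
  rates, adoption pulls a lagging camp back toward its neighbours at
  rate `phi1 * difference * neighbours`, so cultural loss rarely wins in
  a connected group and mean complexity grows near-linearly through a
  2 000-year window — there is no saturation. The regime in which
  complexity fluctuates about a population-dependent level (what a
  120 000-year run spanning dozens of landscape epochs probes) is not
  reachable in so short a window without rescaling the cultural rates.
  The raw camp-count/complexity Pearson correlation at desk scale is
  therefore dominated by the interaction of two trends — the landscape
  realization's richness trajectory, which drives camp numbers, and the
  complexity ratchet — and is typically negative in all three adoption
  conditions. The corresponding acceptance-style expectation (positive,
  adoption-ordered correlations) is a full-scale phenomenon and is
  deliberately *not* reproduced by these desk-scale tests; the test
  encoding it documents this as a failing check rather than asserting a
  weakened claim.

* The ethnographic-scale mobility statistics (about 9 moves/yr) emerge
  only under a full 120 000-year landscape stack and its scaling;
  at desk scale with `sigma0` = 0.4 km month^-1/2, monthly displacements
  rarely clear the 2 km move threshold, so move counts are small and the
  mobility statistics are noisy. The statistics pipeline is exercised and
  tested regardless.
* Within-camp individual mobility, age/sex structure, trait-dependent
  survival, conformity/prestige bias and culture-to-mobility feedback are
  out of scope by design.
* Geodesy is ignored: coordinates are planar km.
* The cultural event log can dominate memory on long runs; sweeps disable
  it (`log_cultural_events: false`) and rely on the metrics series.
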