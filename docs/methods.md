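# Methods

## The question

Cross-sectional microbiome surveys measure species abundances once per host,
across many hosts. A common analysis infers an "interaction network" from
co-occurrence: compute (partial) correlations between taxa across hosts and
call significant pairs interactions. This package asks, by simulation against
a known ground truth, when that inference works: which ecological interaction
types are recoverable from abundance correlations, and how the answer depends
on host-to-host variability, noise, network structure and sampling time.

## The model

Within each host *m*, species abundances follow generalized Lotka-Volterra
(gLV) dynamics,

    dN_im/dt = r_im · N_im · (1 − N_im/K_im + Σ_{j≠i} α_ij,m · N_jm),

with intrinsic growth rate `r_i`, carrying capacity `K_i` (self-limitation
`α_ii = −1/K_i` is folded into `K` so the interaction matrix `A` holds only
interspecific terms, mirroring what a correlation matrix could at best
recover), and signed per-capita interaction coefficients `α_ij` (effect of
species *j* on species *i*). The sign pair (α_ij, α_ji) defines the pair's
ecological type: mutualism (+,+), competition (−,−), commensalism (+,0),
amensalism (−,0), exploitation (+,−).

For the two-species system the interior equilibrium is closed-form:

    N1* = K1 (1 + α12 K2) / (1 − α12 α21 K1 K2),

symmetrically for N2*; it is stable iff the denominator is positive, and
coexistence additionally requires both equilibria positive. The numerical
integrator is validated against this formula to 1e-6, and the analytic
coexistence region is cross-checked against survival of the integrated model.

## Synthetic communities

Species-level parameters per community (the "base case", 10 species):

| parameter | distribution | notes |
| --- | --- | --- |
| r_i | U(0.05, 0.1) per time unit | sets approach speed only |
| K_i | U(0, 1) abundance units | draws of exactly 0 rejected |
| topology | each ordered pair present w.p. 1/4 | Bernoulli, not exact count |
| α_ij | equal mixture N(±0.25, 0.1), truncated to (−0.5, 0.5) | rejection resampling, not clipping |

Host-level replicates (300 hosts) are lognormal around the species values:
`ln|α_ij,m| ~ N(ln|α_ij|, σ_α)` with the original sign restored (σ_α = 0.25
in the base case), and likewise for `r` and `K` (σ_r = σ_K = 0 in the base
case). Presence and sign of every interaction are conserved across hosts;
host-level magnitudes are not re-truncated at 0.5 (truncation applies to the
species-level draw only).

Alternative structures:

* **Producer–consumer.** Equal producer/consumer blocks. Cross-feeding and
  shared-resource competition are two-way relations, so each selected
  unordered pair carries both directed coefficients: between-block pairs from
  the positive mixture component (mutualistic cross-feeding), within-block
  pairs from the negative component (resource competition). Ordered-pair
  density stays at the configured value. Independent per-direction placement
  was tried first and discarded: it leaves the symmetric-pair fraction at the
  base-case level and erases the recall advantage that defines this network
  family.
* **Hubs.** Union of two directed preferential-attachment graphs (power 2,
  one edge per vertex step, via igraph), then uniformly random edges
  added/removed to hit the target density. Both graphs are oriented alike, so
  hub interactions are predominantly one-directional; transposing one graph
  before the union was tried and discarded because it symmetrizes the pairs
  around the hubs and turns the hub scenario into an easier, not harder,
  inference problem — the opposite of what hub-dominated networks do.
* **30 species** at density 1/6 (sparser, to keep coexistence attainable).

## Simulation

All hosts of one community are integrated as a single block-diagonal system
with a vectorized right-hand side (explicit Runge-Kutta, rtol 1e-6, atol
1e-9, recorded every 1 time unit to horizon 1000). Initial abundances are
half the host-specific carrying capacity — the model does not prescribe them;
this choice is strictly positive, scale-appropriate, and keeps transients
comparable across hosts. Integration error at these tolerances (~1e-6) is
three orders of magnitude below the measurement noise, so it cannot influence
inference; analytic-agreement tests use rtol 1e-10.

**Extinction screening.** A parameter set is rejected and redrawn whenever
any species in any host drops below 0.001 at any recorded time (retry cap
100). A cheap pre-screen integrates the species-level (no host variation)
system first; since hosts are lognormal around it with median equal to it, a
failing species-level system would essentially always fail somewhere among
300 hosts. Rejection rates are low (~10 per 100 accepted sets in the base
case).

**Process noise.** Every Δt = 1 the state is multiplied elementwise by
exp(ε), ε ~ N(0, σ_W) — a discrete multiplicative lognormal shock that keeps
abundances positive (σ_W = 1 "high", 0.1 "low"). The continuous-time
formulation of this scheme is genuinely ambiguous in the tradition this
design follows; the discrete multiplicative reading is this package's
choice. Survival screening for noisy runs uses the deterministic skeleton
only: any σ_W > 0 makes transient threshold dips certain over 1000 shocks ×
3000 species-host pairs, so screening the noisy path would reject every set.

**Perturbation.** During [175, 225] every carrying capacity is replaced by a
fresh U(0, 1) draw and restored afterwards; communities relax back to their
original equilibrium. Survival is assessed before the window and at the
horizon, not during/after it — transiently depressed abundances inside the
window are the perturbation working as designed, and species regrow once
capacities are restored. Default within-window sampling times are t1 = 176,
t2 = 190, t3 = 210, t4 = 224, with t5 = 1000 at the recovered equilibrium
(the source design marks but does not print these; they are configurable).

**Sampling.** The hosts × species matrix is read off the recorded grid at
one timepoint (or per-host uniform random times on [100, 1000], snapped to
the grid) and i.i.d. measurement noise U(−υ, υ) is added without clipping
(υ = 0.01 base; 0.001 low; 0.1 high).

## Inference

Partial Pearson correlations of every species pair given all remaining
species come from the inverse correlation matrix, ρ_ij = −P_ij/√(P_ii P_jj);
a residual-regression implementation serves as an independent oracle in the
tests (agreement to 1e-10). Significance uses the exact t-transform
t = ρ·√(df/(1−ρ²)) with df = n − 2 − (s − 2) conditioning correction
(standard under Gaussian residuals; the tradition this follows names only
"significant partial correlations"). The Benjamini–Hochberg step-up
procedure is applied to the s(s−1)/2 lower-triangle tests of one dataset
(never pooled across replicates); an edge is called at adjusted p < 0.05.
Singular correlation matrices are reported, never silently regularized. No
compositional transform is applied: the simulated abundances are absolute.

## Scoring

Unordered pairs only (a correlation matrix is symmetric; `A` is not). Each
pair lands in one confusion cell per matching rule:

* *either_sign*: a significant correlation matching the sign of either
  nonzero coefficient is a true positive. This credits both signs on
  exploitative pairs — a deliberate, acknowledged bias of the lenient rule.
* *strongest_sign*: the intended sign is that of the larger |α|; exact-tie
  pairs accept either sign (symmetric exploitation genuinely produces both).
* *strict_both*: both coefficients' signs must be reflected, so only
  mutualism and competition are recoverable; a significant correlation on an
  asymmetric interacting pair counts as a false positive (the call asserts a
  symmetric relation the truth lacks), not a false negative.

Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, with
0/0 defined as 0. TP(strict) ≤ TP(strongest) ≤ TP(either) holds by
construction and is property-tested. Per-type detection rates count
significant sign-matching pairs per ecological type.

Scenarios are compared by two-sided Mann–Whitney U on per-replicate F1;
all-identical inputs are flagged degenerate (p = 1 by convention).

## Replication scale and seeds

The full-scale design is 1000 replicate networks per scenario; the package
default is 100, at which every directional comparison reported here is
stable and a full scenario runs in ~15–60 s on one core. One master seed
expands to per-replicate streams via counter-based `SeedSequence` spawning,
so replicates are independently reproducible and rejected draws do not
consume replicate indices. Scenario variations redraw parameter sets
independently (whether the original design reused them across scenarios is
unstated; comparisons are unpaired either way).

## What the generator does and does not emulate

The simulations emulate: host-to-host fold-change variation in dynamical
parameters, observation error, environmental shocks, non-equilibrium
sampling, and structured interaction networks. They do not emulate:
compositionality (sequencing yields relative abundances; here they are
absolute), zero inflation and detection limits, taxa absent from some hosts
(all species are omnipresent; signs and presence of interactions are fixed
across hosts), higher-order or time-varying interactions, or alternative
stable states. Passing tests therefore show what correlations can do under
idealized gLV conditions — results transfer to real surveys only insofar as
those conditions hold, which is precisely the caveat the analysis
illustrates.

## Numerical and degenerate-input choices

* Truncation by rejection resampling (no boundary atoms).
* K = 0 draws rejected (the dynamics divide by K); perturbation redraws
  likewise.
* Partial correlations require n_hosts > n_species + 2 and non-constant
  columns; condition numbers above 1e12 raise.
* ρ = 0 maps to p = 1; |ρ| = 1 to p = 0.
* Extinction threshold crossings are checked on the 1-unit recording grid,
  not only at the sampling time.
* Equilibrium flag: max |dN/dt| < 1e-8 at the horizon (informational; with
  the default rtol a converged run may sit ~1e-7 from the fixed point).

## Known limitations

* The t-test for partial correlations assumes Gaussian residuals; gLV
  equilibria plus uniform noise are only approximately so. The null
  false-discovery check (mean falsely-significant fraction ≤ 0.05 over 500
  null datasets) verifies the operating characteristic that matters here.
* Detection rates per type need O(100) replicates to stabilize; single-seed
  small runs can reorder adjacent types.
* The process-noise and hub constructions follow this package's documented
  readings of ambiguous source descriptions (see above); both are
  configurable enough to explore alternatives.
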