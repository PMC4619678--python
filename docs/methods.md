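# Methods

This note documents the statistical models behind `standstruct`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions that make results reproducible.

## Data model

A plot is a rectangular window (default 50 × 50 m, 0.25 ha) with one row
per tree: coordinates in metres (0-based at the window origin), a species
label, DBH in cm and optionally height in m. Trees below the 7 cm calliper
threshold are outside the measured population and are rejected at load
time with a count of excluded rows. Per-hectare quantities use the
expansion factor 10000/A (× 4 for a 0.25 ha plot); diameter classes are
10-cm bins starting at the calliper threshold, [7, 17), [17, 27), …, and
`fcd` denotes the relative frequency of the first bin. The
dominant/suppressed stratification sorts trees by descending DBH (ties by
ascending row index) and takes the smallest prefix holding 50% of the
stand basal area as the dominant class — the basal-area-of-larger-trees
logic of classical competition indices.

## Edge handling for neighbourhood indices (NN1)

The three indices average a per-tree quantity, so edge trees whose true
nearest neighbours may lie outside the plot would bias the plot mean. The
NN1 rule used here admits a tree as a *reference* tree only when the
distance to its k-th nearest neighbour (k = 1 for CE, k = 4 for the angle
indices) does not exceed its distance to the nearest window edge; all trees
remain candidate neighbours and enter the density estimate. The 4-neighbour
indices additionally require at least 6 trees and a non-empty reference
set; sparse strata therefore fail with an explicit error, which the study
driver renders as "-" cells, the way field reports print them.

Two properties of this rule matter for interpretation:

- The angle-based indices (W, R) depend on neighbour azimuths only. Under
  CSR the azimuths of the k nearest neighbours are iid uniform regardless
  of the conditioning on distances, so W and R remain exactly centred under
  NN1. This gives closed forms: E[W] at threshold α₀ is
  `1 − (1 − α₀/360)³` — 0.488 at α₀ = 72°, the value conventionally
  rounded to 0.5 — and E[R] ≈ 1.799, the resultant-length constant for
  four random unit vectors (reproduced here by simulation).
- CE averages the very distance the rule conditions on, so the NN1 CE is
  biased slightly below 1 under CSR (≈ 0.92 at n = 40, ≈ 0.98 at n = 500
  on a 0.25 ha window). This bias cancels in the Monte-Carlo test, which
  applies the identical rule to the simulated patterns; CE values should
  not be compared to the analytic constant 1 directly at small n.

`null_index_expectation` exposes three edge modes — `nn1` (the estimator's
own rule), `none`, and `torus` (periodic distances, fully edge-free) — so
all of the above can be verified numerically; the torus mode reproduces
CE = 1.00, W = 0.488, R = 1.799.

Angular conventions: azimuth 0° = north (+y), clockwise (the forestry
convention; the indices only use angular gaps and resultant lengths, so any
fixed convention gives identical values). Gaps are compared strictly
(`gap < α₀`). Neighbour ties are broken by ascending tree index.

## Monte-Carlo CSR tests of the indices

The CSR null has no labels to permute, so "randomisation" means fresh
uniform patterns with the observed tree count in the observed window
(default 10,000). Tail probabilities use the add-one estimator
`(1 + #{sim ≥ obs})/(n_sim + 1)`, which never returns 0. The reported tail
is the clustering-direction quantity — `1 − P(Z ≥ CE)` for CE, `P(Z ≥ W̄)`
and `P(Z ≥ R̄)` for the angle indices — read against the two-sided
0.01/0.99 rule: below 0.01 clustering, above 0.99 regularity, otherwise
CSR. With the add-one discretisation the exact null rate of the combined
rule is about 1.9% at n_sim = 999, which the calibration tests check.

## Second-order statistics

Univariate estimator `K̂(r) = (A/n²) Σ_{i≠j} w_ij 1(d_ij < r)` (strict
inequality), with three edge corrections:

- `isotropic` (default): Ripley's circumference-fraction weight — the
  reciprocal of the fraction of the circle of radius d_ij centred on point
  i lying inside the rectangle, with the corner-overlap terms handled in
  closed form. Exact for r up to half the shorter window side, which also
  caps the distance grid (default 0–12 m in 0.25 m steps). This is the
  de-facto standard for rectangular windows; the implementation matches
  spatstat's `Kest` to ~1e-13 after adjusting for spatstat's n(n−1)
  intensity normalisation (this package keeps the plain A/n² definition).
- `translation`: weight A/((W−|dx|)(H−|dy|)).
- `none`: raw pair counts (used by the brute-force equivalence tests).

Cross-type estimator `K̂_ij(r) = (A/(n_i n_j)) Σ w 1(d < r)` over ordered
cross pairs, combined as `K_B = (n_i K_ij + n_j K_ji)/(n_i + n_j)` since
the two directional estimates differ only through edge effects. L
transforms: `L = √(K/π) − r`, zero under CSR (univariate) or independence
(bivariate).

Envelopes are pointwise rank envelopes: the k-th smallest/largest of n_sim
simulated L curves per distance, k = ⌈n_sim(1−level)/2⌉ (rank 5 per tail
at 1,000 simulations and the 99% level). The univariate null re-scatters
the same count uniformly; the bivariate null holds type i fixed and shifts
type j by a uniform toroidal offset (randomised relative position). Note
that at fixed level the effective tail mass k/(n_sim+1) decreases toward
its nominal value as n_sim grows (1/100 at 99 sims, 5/1000 at 1000), so
small simulation counts give slightly liberal (narrower) bands — one
reason the study default stays at 1,000.

Scale classification labels every grid distance `below/inside/above` the
band and phrases contiguous runs with the conventional vocabulary
(clustering/CSR/regularity; aggregation/Independence/repulsion), reporting
run bounds in metres.

The `d_cut` scan operationalises "the split where cross-size aggregation
is most pronounced": for each candidate threshold (default range 7–40 cm)
it computes the small-vs-large bivariate L and its independence envelope
and scores the candidate by the integrated excess of L above the upper
bound (Σ_r max(0, L−upper)·Δr); the arg-max wins, ties going to the
smaller threshold, and a zero maximum is flagged non-significant.
Candidates producing identical group memberships are evaluated once. This
integral score is a reproducible surrogate for the visual inspection such
thresholds are traditionally chosen by. The study driver defaults to the
fixed reference thresholds (23.2 cm for all species, 29.3 cm within the
focal spruce) and re-estimates per plot only when asked, because a full
scan per plot multiplies the envelope cost by the number of candidate
splits.

## Covariation and group differences

The covariation `C` is a pure sign-concordance statistic over all plot
pairs (monotone, not necessarily linear, association). Its permutation
test shuffles Y against X and takes the tail on the side of the observed
sign; consequently the one-sided p lives on (0, ½] and its two-sided
equivalent 2p is what is uniform under independence. An undefined C (zero
denominator, e.g. a constant variable) is reported as a distinct state,
never coerced to 0. Group mean differences are tested by random
reassignment of the pooled per-plot values to the observed group sizes
(two-sided, add-one), with exact enumeration of all C(n, n_a) assignments
when there are at most 20,000 — the reassignment unit is the plot-level
mean, matching how such comparisons are reported. Bonferroni correction is
applied per explicit family with m defaulting to the number of tests
actually run, since composite family sizes are study-specific.

## Synthetic stands

The generators provide every input the pipeline needs:

- `gen_csr`, `gen_thomas` (Poisson parents at κ/ha, Poisson(μ) offspring,
  Gaussian σ displacement, window clipping by re-draw so parent–offspring
  distances stay honest near edges), `gen_hardcore` (simple sequential
  inhibition with a proposal budget that fails loudly, reporting the
  achieved count).
- `gen_marked_stand`: positions from a chosen process; species from a
  mixture; DBH from a truncated exponential on [7, d_max] (rate default
  0.08 cm⁻¹, d_max 90 cm) — a one-parameter reverse-J law matching the
  monotone-decreasing diameter-class profile of uneven-aged stands;
  heights from h = 1.3·dbh^0.75 with lognormal noise (summary marks only,
  never used for inference). The optional size-link places every tree
  below a DBH threshold as a Gaussian offspring of a random larger tree,
  creating the small-around-large aggregation that gap-regenerating
  stands show.
- `gen_study_fixture`: 12 plots named after the study's locations, total
  counts uniform on [38, 133] (152–532 stems/ha), focal-species counts on
  [11, 35] realised exactly, 4–9 species each present at least once,
  alternating CSR and size-linked clustered position processes, and
  latitudes spanning 23.5–28.8° N.

All generators are pure functions of (parameters, seed). What they do not
emulate: topographic/soil covariates, species-specific spatial preferences,
height–diameter allometry fitted to real stands, temporal dynamics, or
measurement error in stem coordinates. Tests passing on these stands
demonstrate the correctness and calibration of the estimators, not
ecological conclusions about any real forest.

## Reproducibility and numerics

One master seed drives a study; each (plot, stage) pair derives its own
`SeedSequence` from the master seed and a CRC-32 of the stage key, so
results do not depend on which optional stages run or in what order. Rerun
with the same configuration, the bundle and its TSV/JSON outputs are
byte-identical (indices printed at 3 decimals, probabilities at 4). kNN
queries use an exact O(n²) table with stable index tie-breaking for
plot-sized inputs and a blocked argpartition path (32-candidate tie
buffer) for large calibration patterns such as the 10⁴-point lattice.

Problem sizes used by the shipped test-suite calibration checks: null-rate
calibration at 400/150 CSR seeds with 499 simulations per test, power
checks at 20 seeds with 999 simulations, null-constant runs accumulating
10⁵ reference trees, and envelope/d_cut checks at 99–199 simulations —
sizes at which the binomial acceptance bounds used in the tests have the
intended resolution while the suite stays fast.

## Known limitations

- The isotropic correction's closed form assumes r ≤ min(W, H)/2; the grid
  constructor enforces this.
- The NN1 CE bias at small n (above) is inherent to the published
  estimator, not removed; inference is unaffected.
- Pointwise envelopes test each distance separately; no global envelope or
  multiple-testing control across distances is attempted, so verdict
  strings can flag isolated single-distance excursions (about 1% of grid
  points under the null).
- The hard-core generator is sequential inhibition, which approximates but
  is not exactly a Matérn process; it serves as a regularity fixture, not
  as a fitted model.
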