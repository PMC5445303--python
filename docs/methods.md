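# Methods

`magefit` analyses multiplex automated genome engineering (MAGE) fitness
campaigns: a slow-growing engineered bacterium is cycled through pooled
oligo-mediated editing, clones are sampled and phenotyped along the way, and
a regression model over clone genotypes attributes the fitness recovery to
individual alleles.  This note records the models, the defaults and why
they were chosen, and what the synthetic-data generator can and cannot
stand in for.

## Doubling time from kinetic OD600 curves

A clone's doubling time is

    t_double = c · ln(2) / m,

where `c` is the sampling interval in minutes per time point (default 5)
and `m` is the maximum slope of ln(OD600) per time point over all sliding
windows of `window_points` contiguous readings (default 8, i.e. 40 min).
Each window slope is a closed-form least-squares fit of log OD against the
point index; ties between equally steep windows break to the earliest
start, for determinism.  Readings are clamped to `od_floor` (default 1e-4,
far below real signal) before the log so blank-subtracted zeros cannot
produce −inf.  No smoothing or trimming is applied: the max-slope window
intrinsically ignores lag and stationary phases, which is why the method
works on curves that differ in shape or never reach the same final density.

**Known bias.** Maximising over windows selects, among windows with the
same true slope, the one noise has steepened.  With iid per-point
multiplicative noise of CV σ the estimate of t_double is therefore biased
low — about −2% at σ = 0.01 and −8% to −13% at σ = 0.05 for curves offering
five or more windows (measured by Monte-Carlo; the bias vanishes as σ → 0
and for single-window curves).  At realistic plate-reader noise in log
phase (σ ≲ 0.01) the bias is small against biological replicate variation,
but doubling times estimated this way should be compared only with other
values estimated the same way.  The test suite freezes this behaviour.

Fitness is normalised as the percent of the start strain's defect
recovered, `100·(t_start − t_clone)/(t_start − t_parent)`; values below 0
(slower than start) and above 100 (faster than parent) are legal.
Replicate wells are reported per well plus a per-clone mean — the
aggregation is this package's own convention.

## Candidate-mutation filters

Three filters reduce an annotated variant list to oligo-pool candidates:

* **Coding filter** — include every frameshift, nonsense, nonsynonymous and
  non-coding-RNA mutation, plus synonymous mutations in genes whose Keio
  knockout grows to less than 0.7 of wild type after 22 h in LB
  (`LB_22 < 0.7`).  Synonymous mutations with no LB_22 annotation are
  excluded with a warning.
* **Priority categories** — included mutations are sorted into nested pools
  P1 ⊆ P2 ⊆ P3.  The mapping used here (category 1 = frameshift/nonsense or
  any included class in an essential gene; 2 = remaining nonsynonymous and
  non-coding RNA; 3 = qualifying synonymous) is an approximation: published
  category assignments were tabulated per mutation rather than stated as a
  rule, so the exact rule is not recoverable.
* **Regulatory filter** — on precomputed scores only: a mutation is flagged
  if the mean minimum free energy of the 5′ mRNA fold (averaged over the
  (−30,+100) and (−15,+100) windows around the start codon) changes by more
  than 10% relative to the wild-type context, or if predicted
  ribosome-binding-site expression changes more than 10-fold in either
  direction.  The package never computes folding or RBS strength itself.

Alternate-fraction (AF) genotype calls classify as strong (AF ≥ 0.7),
marginal (0.1 < AF < 0.7) or absent (AF ≤ 0.1); the marginal band is an
open interval, so the boundaries resolve outward (0.1 → absent,
0.7 → strong).  Downstream, marginal calls are treated as missing
genotypes; the default policy imputes 0 with a warning (conservative:
biases toward no effect), with clone-dropping available.

## The multiplicative allele-effect model

Each allele is assumed to act multiplicatively on doubling time, so on
y = ln t_double the model is linear with coefficients interpretable as
Δln doubling time per allele copy (negative = beneficial).  Natural log is
used; the base only rescales coefficients.  Fitting minimises the
elastic-net penalised loss

    L(λ1, λ2, β) = |y − Xβ|² + λ1|β|₁ + λ2|β|²,

parameterised as alpha = λ1 + λ2 and l1_ratio = λ1/(λ1 + λ2).  The
l1_ratio grid [0.1, 0.3, 0.5, 0.7, 0.9, 0.95, 0.99, 1] is dense near the
L1-only end, matching the prior that few alleles carry most of the effect;
alpha is searched over `n_alphas` (default 100) values log-spaced from the
smallest alpha that zeroes every coefficient down by three decades
(`path_eps` = 1e-3), with 5-fold cross-validation choosing both.  The
binary design matrix is not standardised (features already share a scale)
and the intercept is unpenalised.  Fitting is delegated to coordinate
descent (scikit-learn); the test suite independently verifies the returned
coefficients satisfy the subgradient stationarity conditions of the loss
above under the mapping λ1 = 2n·alpha·l1_ratio, λ2 = n·alpha·(1−l1_ratio)
(the fitter divides the squared error by 2n).

**Feature construction.** Alleles observed in fewer than
`min_clone_occurrence` clones (default 2) are dropped; constant columns are
retained but flagged non-identifiable.

**Repeated weighted fits.** Because the design is undersampled, one CV fit
is unstable.  The procedure repeats it `n_reps` times (default 100), each
time holding out `n_holdout` clones (default 15) drawn without replacement
from a seeded generator, and weights each repetition by its holdout
R²; negative scores clamp to zero so non-predictive repetitions get no
weight (the weighting rule leaves negative-score handling open; clamping
is the conservative choice).  If every weight is zero the unweighted mean
is used with a warning.  Per-repetition seeds derive from the master seed,
making the whole procedure bitwise reproducible.

**Two rounds.** Features with a negative weighted-mean coefficient advance
to a second, identical round restricted to the survivors, with
hyperparameters re-selected from scratch (re-selection is assumed; the
alternative of freezing round-1 hyperparameters was not described).  The
round-2 weighted means rank the selection; ties break by occurrence count,
then id.  Per-repetition selection frequency is surfaced so users can see
which weak effects are split-dependent.

Reduced-cost profile: procedures that wrap many CV fits (the power sweep,
experiment-scale tests) run with n_alphas ≈ 20–30, path_eps ≈ 0.02–0.05 and
n_reps ≈ 15–25.  The selection gate only needs the sign of the weighted
mean, which stabilises well before 100 repetitions; spot checks at the full
settings agree.  These sizes are the package's documented desk-scale
defaults for sweeps, not a change to the single-fit defaults.

Small validation panels (≤ 10 alleles, guard: features ≤ clones/3) use
unregularised OLS with classical t-tests, and a univariate one-allele-at-a-
time scan is provided as the GWAS-style comparator — on passaged
populations it cannot separate hitchhikers from causal alleles, which is
the motivation for the joint penalised model.

## Pairwise epistasis

For a small set of validated alleles, OLS of ln t on all main effects plus
all pairwise products gives interaction coefficients with t-test p-values.
Interactions are Bonferroni-controlled at a family-wise error rate over the
C(n, 2) pairs (0.05/15 ≈ 0.003 for six alleles); main effects are reported
uncorrected, matching the convention that only the interaction family is
being screened.  Positive interaction coefficients on the log scale mean
diminishing returns; negative mean synergy.

The background-recovery analysis groups clones by exact genotype at the
non-focal alleles (no pooling of similar backgrounds) and, per background
with both focal states present, compares mean recovery gained against the
no-epistasis multiplicative prediction
y(x) = 100·(1 − e^β)·t_bg/(t_start − t_parent), where x is the background's
remaining defect in percent of the original defect and
t_bg = t_parent + (x/100)(t_start − t_parent).  Percent units are anchored
to one (t_start, t_parent) pair per analysis.  Points below the curve
indicate diminishing returns.

## The synthetic-data generator

`mage_sim` emulates the statistical structure of a MAGE fitness campaign,
not its sequences: no reads, no reference genome, no oligo thermodynamics.
Per cycle, each cell independently converts each unedited target with
probability q = 1 − (1 − p_any)^(1/n_oligos), so the aggregate chance of at
least one edit is `p_any_edit_per_cycle` (default 0.15, inside the
empirical 10–20% MAGE range); edits are never lost.  De novo mutations
arrive Poisson(`de_novo_rate_per_cycle`, default 1.0 — the hypermutator
regime of mismatch-repair-deficient MAGE strains), 95% exactly neutral and
5% causal with effects ~ Normal(0, 0.05) truncated to ±0.2 on the log
scale.  True log doubling time is ln t_start + Σβx + Σγxx.

Selection between cycles is multinomial resampling weighted by
2^min(60h/t_double, max_doublings), with h = `selection_hours_per_cycle`
(default 5, a typical post-MAGE recovery outgrowth) and
`max_doublings_per_cycle` = 10 modelling confluence: within a finite batch
outgrowth a culture saturates, so speed below ~30 min/doubling buys no
further advantage.  Without the cap, compounding beneficial de novo sweeps
drive doubling times to biologically impossible values over 50 cycles.
This is a minimal population model — constant population size, no explicit
lineage structure, no mechanism of recombination — chosen because only the
allele-frequency and hitchhiking structure matters downstream.

Sampled panels take `clones_per_sample` clones (without replacement) at
each listed cycle before that cycle's resampling, plus `n_start_clones`
(default 3) unedited start-strain clones measured at cycle 0, mirroring
real panels that include the parent as baseline — and guaranteeing that an
allele swept to fixation still varies across the panel.  Measured doubling
times carry multiplicative lognormal noise of CV `measurement_cv` (default
0.05, typical clone-to-clone assay repeatability).  Defaults for the
reference experiment: 26 targets, 50 cycles, population 1000, panels of 9
clones at cycles 5,10,…,50 (≈ 90 clones), start strain at
t_start = 40 min vs parent t_parent = 25 min — a 60% doubling-time excess,
ln(1.6) on the log scale.

What passing tests on this generator do **not** show about real data:
genotyping error and marginal-call ambiguity are not generated (missing
values must be injected explicitly); lineage structure is cruder than three
separately cycled oligo pools; de novo effect sizes follow a stylised
distribution; and measurement noise is homoscedastic.  Conclusions about
the *procedure* (ranking behaviour, false-positive control, power) transfer;
conclusions about specific biological effect sizes do not.

A separate helper, `simulate_construction_clones`, generates
construction-intermediate-style panels (each allele present independently
with probability 0.5, multiplicative phenotype with optional planted
interactions) for the epistasis analyses, where combinatorially mixed
genotypes rather than cycling structure are what matters.

## Power analysis

`run_power_sweep` simulates full experiments per grid cell
(n_causal × n_clones), with the total log defect (default ln(1.6)) split
across the causal reversions (equally by default, or by a 0.7-ratio
geometric sequence), runs the two-round selection on each simulated panel,
and scores each replicate by the detection fraction: the |β|-weighted
recall of the selected set,

    detection = Σ_{selected ∩ causal} |β| / Σ_{causal} |β|.

The published statement being operationalised gives no formula; weighted
recall is the natural reading, and in the no-epistasis multiplicative model
it coincides with the fraction of the log defect the selected alleles
jointly explain (an equivalent scorer is exposed for that framing).
Holdout size scales down with small panels (≈ 1/6 of clones, capped at 15)
so the 15-of-90 default generalises.  Replicate seeds derive from the
master seed and grid-cell index.  At the experiment-scale cell (8 causal,
~90 clones, no epistasis) mean detection over 20 replicates exceeds 90% —
the design's headline property, recomputed from scratch by
`scripts/acceptance.py`.

## Numerical conventions and degenerate inputs

* Coordinate-descent tolerances: single fits 1e-4 (relative), exactness
  checks 1e-10…1e-12; the zero-penalty limit reproduces OLS to 1e-6.
* Rank-deficient OLS designs raise with the collinear features named;
  interaction designs name inestimable terms via a greedy independent
  column scan.
* Curves with no positive-slope window raise a no-growth error; plates with
  irregular time axes name the offending index.
* Genotype files: missing is literal `NA` or an empty cell, never 0; clone
  ids must be unique; parsing is locale-independent.
* All stochastic procedures take explicit integer seeds and are
  reproducible bit-for-bit given the same seed and library versions.
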