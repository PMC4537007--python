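# Methods

This note documents the models, defaults and numerical choices behind
`mirmodscore`, and what the synthetic-data generator does and does not
emulate.

## Factorial selection

Each feature is decomposed by the standard balanced two-factor ANOVA with
replication: SS for factor A (first drug), factor B (second drug) and the
A×B interaction, each on 1 df, against the within-cell residual on n−4 df.
For balanced designs the closed-form sums-of-squares are computed vectorized
over all features; a test cross-checks them against the equivalent OLS
cell-means model, and unbalanced designs fall back to a per-feature OLS fit
(type-II ANOVA) behind an explicit flag. Zero-variance features return
p = 1 with a `degenerate` flag rather than being dropped, so downstream
joins never lose ids.

Selection uses **unadjusted** p-values against α (default 0.01 for the miR
matrix, 0.001 for the mRNA matrix). This interprets the conventional
"two-way ANOVA, p < 0.01" selection rule as a raw threshold; a BH-adjusted
mode is available (`adjust=True`). The two time points of a typical design
(miRs and mRNAs profiled at different times) are metadata only: both
matrices go through the same operation.

The detectable-expression filter keeps features whose per-condition mean
exceeds the threshold in **at least one** of the four conditions.

PCA of treatment effects centers each feature (no scaling by default;
`scale=True` available) and takes the SVD of the sample-by-feature matrix;
coordinates are the first two principal components of the samples.

## Target integration

A pair survives when (1) any prediction source lists it and (2) Spearman
ρ < −0.9 with BH q < 0.05, both comparisons strict. Choices:

* **Correlation axis.** By default profiles are paired per sample
  (`axis="samples"`); `axis="condition_means"` pairs the four per-condition
  means instead, for designs where the two matrices' samples do not
  correspond. With 4 untied points the achievable Spearman values are
  {−1, −0.8, −0.6, …}, so ρ < −0.9 is then satisfiable only by perfect
  anti-ranking, and the smallest achievable exact two-sided p is 1/12 —
  condition-mean profiles therefore cannot pass a q < 0.05 filter on their
  own. This granularity is why per-sample pairing is the default.
* **Ties** get average ranks (rank-Pearson formula).
* **P-values.** For profile length ≤ 8 the two-sided p is exact by
  permutation (for untied profiles the null distribution depends only on n
  and is cached; tied profiles enumerate permutations directly). Longer
  profiles use the large-sample t approximation. The t approximation is
  anti-conservative in the far tail (the regime BH probes when many pairs
  are tested): in a null simulation with 100 pairs of length 24 the
  familywise rate at q < 0.05 was ≈0.07 rather than 0.05. The calibration
  test therefore exercises the exact-permutation path, and far-tail
  q-values obtained through the t approximation should be read as
  approximate.
* **BH family.** All candidate pairs are adjusted as one family (not
  per-miR). Pairs with constant profiles have undefined ρ and are excluded
  with a logged count.

## Network modules and connectivity

The integrated edges form a bipartite graph (identifier collisions between
the miR and mRNA namespaces are rejected). Community detection is
method-pluggable: greedy modularity maximization (default), connected
components, or label propagation. Nodes and edges are inserted in sorted
order so results do not depend on hash randomization. Communities are
ranked by **average within-community miR degree** — the criterion that makes
"Module-1" the most connected module — with ties broken by community size
and then smallest member id; the top `n_top` (default 4) become modules,
everything else is `no_module`.

Per-stratum statistics follow avg DOC = 2E/(n_miR+n_mRNA),
avg miR DOC = E/n_miR, avg mRNA DOC = E/n_mRNA with edges counted inside
the stratum. **Attribution rule:** the No-Module row absorbs every edge not
internal to a ranked module (cross-module edges and edges among unassigned
nodes alike), so within-stratum edge counts sum exactly to the network
total. Reported averages are rounded half-even to 2 decimals; full
precision is retained internally.

Module direction weights (+1/−1) are the sign of the module miRs' mean
combination-treatment log2 fold-change. For a module whose two drugs act in
opposite directions (a "Module-4"-like pattern) the combination fold-change
is near zero and the assigned sign is data-dependent; such modules
contribute little signal either way.

Over-connected miRs use a strict degree > 50 comparison.

## Signature scores

score = Σᵢ wᵢ xᵢ with wᵢ ∈ {+1, −1}. Normalization modes for xᵢ:
`zscore_per_mir` (default for cohorts without matched normals — the choice
for a TCGA-style cohort, where no normalization is dictated by the data),
`log2_ratio_vs_matched_normal` (default when matched pairs exist; drops
unmatched samples), `raw`. The mode and the effective signature size
(missing miRs are dropped, never imputed) are recorded in the output.
Exact identities hold by construction and are asserted in tests: negating
all weights negates all scores; the impact score equals the general score
of the signature restricted to the over-connected subset.

## Clinical association

* Progression/stage/size: one-way ANOVA with per-group n / mean / SE;
  all-pairs Tukey HSD as post-hoc.
* Matched tumor–normal: paired t on normal−tumor differences; a
  zero-variance difference vector is flagged degenerate instead of
  producing an infinite t. The unmatched-tumor group mean is reported
  alongside for the three-bar comparison.
* Proliferation: Pearson r, two-sided p.
* Survival: samples are split at the empirical 25th/75th score percentiles
  with **strict** inequalities (boundary-inclusive mode behind a flag);
  Kaplan–Meier curves and the log-rank test compare the two quartile
  groups, and a Cox proportional-hazards model regresses survival on
  upper-quartile membership plus covariates. Ordered categories (size,
  stage) enter as treatment-coded dummies against their first level. A
  configurable floor (default 10 events) guards against uninformative fits;
  Cox convergence failures are reported, never silently ignored. Quartile
  membership (matching the KM stratification), not the continuous score,
  is the Cox exposure.
* No multiplicity correction is applied across the association panels
  (each is reported with its own p); a BH summary table is emitted
  alongside for transparency.

Standard procedures (ANOVA, t, Tukey, Pearson, KM, log-rank, Cox,
hypergeometric test, BH) are computed with scipy / statsmodels / lifelines;
each is additionally verified against an independent brute-force
implementation or a null-calibration simulation in the test suite, so the
pipeline's use of them is checked rather than assumed.

## Enrichment

Upper-tail hypergeometric p for the overlap of a query gene set with each
collection set, BH FDR across the collection, one-sided
(over-representation only). The background universe defaults to the union
of collection members when reading GMT files and should normally be set to
all genes on the expression platform.

## Synthetic-data generator

The generator defines the study conditions the tests run under.

* **Treatment experiment.** 4 conditions × 5 replicates. Four planted
  modules of (8, 6, 5, 4) miRs and (65, 55, 33, 25) target mRNAs. Each
  module has an (A, B, interaction) log2 effect pattern — defaults emulate
  one module up-regulated mainly by drug B and enhanced in combination, one
  down-regulated mainly by drug A, one up-regulated mainly by drug A, and
  one pushed in opposite directions by the two drugs. MiRs carry the
  pattern times a positive per-feature multiplier; their targets carry the
  negated pattern, so true pairs anti-correlate across samples. A
  per-sample module-activity component (SD 0.25) is shared with opposite
  sign between a module's miRs and targets, modeling coordinated biological
  variability; residual noise is additive Gaussian on the log2 scale
  (SD 0.2). Baselines are Normal(8, 1) log2 units; planted features sit at
  least 1 log2 unit above the detection threshold (6.0), and 30 % of
  non-planted features are generated below it. With these defaults most
  planted pairs pass ρ < −0.9 and the two largest modules' miRs exceed
  degree 50, so an over-connected subset exists, as in the study design
  this emulates. The sizes are desk-scale stand-ins: the generator does
  not simulate probe-level artifacts, batch effects, or realistic
  microarray intensity distributions, so passing tests demonstrate the
  correctness of the pipeline's logic and calibration, not performance on
  real arrays.
* **Predictions.** Each source lists each true edge with probability 0.8
  and each non-edge with probability 0.001, independently per source —
  a sensitivity/specificity caricature of sequence-based predictors, with
  no sequence model behind it.
* **Cohort.** Default 500 tumors (993 used where the full-size cohort
  matters); `round(n × matched_fraction)` tumors (fraction 102/993) get
  matched normals. A latent score is standard normal minus 0.5 per ordinal
  step of the size/stage categories, then standardized; signature miR
  expression loads on it with sign = module weight (loading 1.0, noise
  SD 0.4), proliferation correlates negatively with it (slope 0.6), and
  matched normals are shifted by +1 log2 unit in the direction of each
  miR's weight. Survival is exponential with
  log-hazard = −0.7 × score and administrative censoring at 10 years
  (baseline hazard 0.12/year) — the simplest model under which Cox recovery
  is well-posed; no competing risks or time-varying effects.
* **Reproducibility.** Each output block draws from its own RNG stream
  spawned from the master seed, so adding a block never perturbs another;
  identical seeds give byte-identical outputs.

## Problem sizes used in validation

Oracle-equivalence checks run ≥100 random small instances per primitive.
Null calibrations use 1,000 replicates at n = 200 (the factorial
calibration uses 2,000 null features in one 200-sample design). Cox
parameter recovery uses 200 cohorts of n = 500 with low measurement noise
(SD 0.1) so the quartile contrast of the latent score is the planted
estimand; the planted value is compared against each replicate's 95 % CI.

## Known limitations

* The anti-correlation filter's q-values rely on the t approximation for
  profiles longer than 8; far-tail q-values are approximate (see above).
* Module detection on real, noisy networks is algorithm-dependent; the
  package treats it as pluggable and validates on planted partitions where
  all methods agree.
* The enrichment module ships no annotation content; results depend
  entirely on the user-supplied GMT and background.
* The generator's distributional choices (Gaussian noise, exponential
  survival) are stand-ins, not fitted to any dataset.
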