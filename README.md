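# mirmodscore

Integrated miRNA–mRNA analysis for drug-perturbation experiments: from a
2×2 factorial expression design to regulated-miR selection, anti-correlation
target integration, bipartite network modules, signed signature scores, and
their association with tumor progression and overall survival in a clinical
cohort.

The package is written for computational biologists who have (a) miR and
mRNA expression matrices from a two-drug factorial experiment (e.g. vehicle /
drug A / drug B / combination, with replicates), (b) candidate miR→mRNA
predictions from sequence-based tools, and (c) a cohort expression matrix
with clinical annotations — and who want a tested, reproducible version of
the classic integrate-then-score workflow. A synthetic-data module generates
all three input classes with planted ground truth, so every stage can be
validated end to end without any external download.

## The method

1. **Detection and selection.** Features whose per-condition mean exceeds a
   detection threshold in at least one condition are kept. Each feature is
   then tested by a two-way ANOVA with replication on the 2×2 design
   (factors A, B, and A×B interaction); a feature is *regulated* when any of
   the three factorial p-values falls below α (default α = 0.01 for miRs,
   0.001 for mRNAs, unadjusted).
2. **Target integration.** A candidate pair (miR *i*, mRNA *j*) survives when
   it is predicted by at least one source **and** the two expression profiles
   are strongly anti-correlated: Spearman ρ < −0.9 with Benjamini–Hochberg
   q < 0.05 (both strict).
3. **Network modules.** Integrated pairs form a bipartite graph. The degree
   of connectivity (DOC) of a miR is its number of targets; of an mRNA, its
   number of regulators. Community detection ranks the top modules by
   average within-module miR degree; per-stratum statistics are
   avg DOC = 2E/(n_miR + n_mRNA), avg miR DOC = E/n_miR,
   avg mRNA DOC = E/n_mRNA. MiRs with degree > 50 are *over-connected*.
4. **Signature scoring.** Each module carries a direction weight
   w ∈ {+1, −1} (the sign of its miRs' regulation by the drug combination).
   For a sample with normalized expression xᵢ, the similarity score is
   Σᵢ wᵢ xᵢ — over all signature miRs (*General Score*) or over the
   over-connected subset (*Impact Score*), with per-module variants.
5. **Clinical association.** Scores are tested against progression stage
   (one-way ANOVA), matched tumor/normal status (paired t), size/stage
   categories (ANOVA + Tukey HSD), proliferation (Pearson r), and overall
   survival (Kaplan–Meier curves and log-rank for the upper vs lower score
   quartiles, plus a Cox model adjusted for size and stage).
6. **Enrichment (optional).** Module target-gene sets are tested for
   over-representation in any GMT collection by the hypergeometric
   upper-tail test with BH FDR.

## Worked example

```python
from mirmodscore import (
    SimulationConfig, simulate_experiment, simulate_predictions,
    detect_expressed, factorial_select, union_candidates, spearman_pairs,
    integrate, build_network, detect_modules, assign_direction_weights,
    connectivity_report, round_report, overconnected_mirs)

cfg = SimulationConfig(seed=1)
mir, mrna, truth = simulate_experiment(cfg)
detected = detect_expressed(mir, cfg.detection_threshold)
diff = factorial_select(mir.subset_features(sorted(detected)), alpha=0.01)
print(f"{mir.n_features} miRs -> {len(detected)} detected -> "
      f"{int(diff['selected'].sum())} regulated")

sources = simulate_predictions(truth, cfg)
edges, counts = integrate(spearman_pairs(mir, mrna, union_candidates(sources)))
net = build_network(edges)
modules = assign_direction_weights(detect_modules(net, n_top=4, seed=1), diff)
print(round_report(connectivity_report(net, modules)).to_string())
```

prints

```
240 miRs -> 175 detected -> 28 regulated
               n_mirs  n_mrnas  n_edges  avg_doc  avg_mir_doc  avg_mrna_doc
Whole Network    23.0    176.0   1031.0    10.36        44.83          5.86
Module-1          8.0     65.0    515.0    14.11        64.38          7.92
Module-2          6.0     54.0    283.0     9.43        47.17          5.24
Module-3          5.0     33.0    151.0     7.95        30.20          4.58
Module-4          4.0     24.0     82.0     5.86        20.50          3.42
No Module         0.0      0.0      0.0      NaN          NaN           NaN
```

The funnel line mirrors the selection stages (all features → detectable →
treatment-regulated); the table gives each module's composition and average
degrees of connectivity. With this seed the four planted modules are
recovered exactly and 10 miRs are over-connected (degree > 50), forming the
Impact-Score subset. Downstream, `simulate_cohort` + `score_samples` +
`survival_by_quartile` reproduce the cohort analyses; the full chain is one
call, `run_pipeline(RunConfig(...))`, or on the command line

```sh
mirmodscore run --seed 1 --outdir run1
```

which writes every stage output plus a provenance manifest.

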