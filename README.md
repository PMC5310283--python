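# panmethyl

Pan-cancer DNA co-methylation module mining.

DNA methylation at CpG probes is summarized by beta values
(methylated / total intensity, in [0, 1]). Across a tumor cohort, groups of
probes whose methylation levels *co-vary* form co-methylation modules —
coordinated epigenetic programs that can recur across cancer types and
separate tumor from normal tissue. `panmethyl` implements a two-step
workflow to find such recurring modules across many methylome datasets and
to score what they do:

1. **Per-dataset module mining.** For each dataset, low-information probes
   are filtered (probes with missing values; variance below the 30th
   percentile; then mean below the 20th percentile of the variance-stage
   survivors), a weighted network is built with edge weights
   `w(i,j) = |Spearman ρ(probe i, probe j)|` over all samples (tumor and
   normal pooled), the weights are balanced by the iterated symmetric
   scaling `W ← D^(−1/2) W D^(−1/2)` until all row sums are 1 (then rescaled
   to unit maximum so thresholds keep an absolute meaning), and modules are
   mined by greedy quasi-clique expansion (lmQCM): seed at the heaviest
   eligible edge with weight ≥ γ, repeatedly add the outside vertex with
   maximal total weight while the density
   `d(C) = Σ_{i<j∈C} w(i,j) / C(|C|,2)` satisfies
   `d_new ≥ α_n · max(γ, d_current)`, `α_n = 1 − 1/(2λ(n+t))`; finally drop
   clusters below the minimum size (20) and merge clusters whose overlap
   ratio `|A∩B|/min(|A|,|B|)` exceeds β. Defaults: γ=0.6, λ=t=1, β=0.4.
2. **Cross-dataset frequent clusters.** Every per-dataset cluster is
   expanded to its complete graph of probe pairs; pairs are pooled over all
   datasets and each pair's count becomes an edge weight (as a fraction of
   datasets). Mining this frequency network with γ = 0.5 yields the
   *frequent* (pan-cancer) clusters — each is seeded by a pair co-clustered
   in at least half of the datasets.

Each frequent cluster is then mapped back into every dataset and
summarized by an SVD **eigengene** (per-sample scores of the first singular
component of the row-standardized probe × sample block; sign fixed so high
score = more methylated), with a rank-based tumor/normal separation AUC
(Mann–Whitney), a Spearman age correlation, cross-dataset Jaccard indices
of gene lists, and edge-contribution percentages.

Because public tumor methylome matrices are large, the package ships a
first-class synthetic-data module: multi-dataset studies with planted
latent-factor co-methylation modules (`beta = invlogit(baseline +
shift·1[tumor] + loading·factor + noise)`), tumor/normal differential
shifts, dataset-specific modules, an X-inactivation-like bimodal control
module, and full ground truth — so every pipeline stage can be tested
against known structure.

## Worked example

```python
from panmethyl import default_study_config, generate_study, run_study

study = generate_study(default_study_config(seed=0))
datasets = list(zip(study.labels, study.betas, study.sheets))
result = run_study(datasets, annotation=study.annotation)

print("frequent clusters:", [c.size for c in result.step2.clusters])
print("pooled probe pairs:", len(result.step2.table.entries))
summary = result.downstream.summary
print(summary.loc[summary.dataset == "D0",
      ["cluster_id", "auc", "direction", "p_value", "age_scc", "age_p"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
```

prints

```
frequent clusters: [30, 30, 30]
pooled probe pairs: 2263
cluster_id     auc   direction  p_value  age_scc  age_p
        F1   0.997  tumor_high 4.28e-16  -0.0782  0.396
        F2 0.00519 normal_high 5.78e-16  -0.0463  0.616
        F3   0.394 normal_high   0.0847  -0.0387  0.674
```

The three 30-probe frequent clusters are exactly the three modules planted
in 4 of the 6 datasets. In dataset D0, cluster F1 (planted tumor
hypermethylation, latent shift +2) has eigengene AUC 0.997 with tumor
samples high; F2 (planted shift −2) separates just as sharply in the
opposite direction (AUC 0.005 ≡ 0.995 with normals high); F3 (no shift)
shows no separation (AUC ≈ 0.4, p 0.08) — the same opposed
hyper/hypo-methylation pattern seen when sorting real tumor cohorts by
module eigengenes. Age, drawn independently of the latent factors, is
uncorrelated with every eigengene (|SCC| < 0.08, p > 0.39).

A CLI mirrors the stages: `panmethyl simulate | preprocess | mine |
frequent | eigengene | compare | run` (see `panmethyl --help`).

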