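# Methods

## Data model

A dataset is a probe × sample matrix of methylation beta values in [0, 1]
with a sample sheet (tumor/normal label, optional age) and a probe
annotation (gene symbols, chromosome). Datasets with fewer than 50 samples
are excluded by the pipeline driver. When two array platforms cover the
same cancer type, the larger platform's probes can be restricted to the
probes shared with the smaller one (`restrict_to_common_probes`) so
clusters are comparable across platforms.

## Probe filtering

Filters are sequential, per dataset:

1. probes with any missing value are removed (no imputation — the simplest
   defensible policy for module mining, where a probe with unreliable
   values should not contribute edges);
2. probes with variance strictly below the 30th percentile of per-probe
   variances are removed;
3. probes with mean strictly below the 20th percentile of per-probe means
   are removed, the percentile computed over the survivors of stage 2.
   Computing the mean threshold on the survivors (rather than on all
   probes) follows from applying the filters in sequence; with smooth
   variance/mean distributions the two readings differ by a few probes at
   most.

Percentiles use linear interpolation between order statistics (the common
statistical default); comparisons at the threshold are strict, so
percentile 0 is a no-op. Sample variance uses denominator n−1 (irrelevant
to the outcome, since the threshold is a percentile of the same values).

## Co-methylation network

Edge weight = |Spearman rank correlation| between two probes' beta values
across all samples of the dataset, tumor and normal pooled. Ranks use
midranks for ties; constant probes get weight 0 everywhere. Rank
correlation makes the network invariant to any monotone transformation of
the beta scale, which also motivates the inverse-logit link in the
simulator.

**Weight balancing.** Before mining, the weight matrix is iterated through
the symmetric scaling `W ← D^(−1/2) W D^(−1/2)` (D = diagonal of row sums)
until `max |row sum − 1| ≤ 1e-4` (cap 100 iterations, error with the final
residual on non-convergence — e.g. on zero patterns with no doubly
stochastic completion, such as trees). This is Sinkhorn–Knopp on a
symmetric matrix, the normalization used for graph Laplacians in spectral
clustering; it removes the bias of greedy mining toward hub-dominated
regions. Symmetry is re-enforced after every iterate to suppress float
drift; tolerance and cap are fixed for reproducibility, and on the dense
correlation networks this package targets, convergence takes ~10
iterations.

**Unit-max rescale.** A doubly stochastic matrix over p probes has entries
of order 1/p, so no fixed absolute seed threshold γ could ever fire at
realistic p. The pipeline therefore rescales the balanced weights by their
maximum before mining, as the published lmQCM implementations do after
normalization; γ then reads as "fraction of the strongest balanced
association in this network". `normalize_weights` itself performs no
rescaling, so its doubly-stochastic contract (row sums 1) is preserved and
testable in isolation.

## Greedy quasi-clique mining (lmQCM)

Parameters: seed threshold γ (step 1 default 0.6, step 2 default 0.5),
decay controls λ ≥ 1 and t ≥ 1 (defaults 1), merge threshold β ∈ (0, 1]
(default 0.4), minimum cluster size 20 (the analysis targets relatively
large modules).

Edges are sorted by weight descending. A new cluster is seeded from the
heaviest remaining *eligible* edge of weight ≥ γ; an edge is ineligible
when both endpoints already co-occur in a previously identified cluster
(an edge with only one endpoint used stays eligible — overlapping clusters
are allowed, which the β-merge presupposes). Growth adds, per step, the
outside vertex with the largest total weight to the current members, and
accepts it iff the resulting density clears

    d_new ≥ α_n · max(γ, d_current),   α_n = 1 − 1/(2λ(n + t)),

with n the current (pre-addition) cluster size. The two arms of the `max`
carry the two published properties of the algorithm: λ and t control the
allowed per-step *decreasing rate* of the density (`α_n · d_current`), and
the absolute floor `density_floor(n) = γ·α_n` bounds the density of every
accepted state from below — a design chosen here because a floor-only rule
measurably over-grows: a tight module whose density sits far above the
floor keeps absorbing background vertices (any vertex whose mean edge
weight only mildly dilutes the average) until the density has decayed all
the way to the floor, which smears planted modules by ~30–40% of their
size on realistic sample counts. The floor formula is isolated in
`density_floor` so it can be swapped.

Ties (equal edge weights, equal candidate gains, equal sizes in merging)
are broken lexicographically by probe id; mining is a deterministic
function of the network and parameters.

After all seeds are exhausted, clusters below `min_size` are dropped, then
any two clusters with overlap ratio `|A∩B| / min(|A|,|B|)` strictly greater
than β are replaced by their union, iterating to a fixed point (scanning in
descending size order and restarting after each merge); unions only grow,
so the size filter needs no re-application, though the pipeline re-checks
it. Merged densities are recomputed from the network.

## Frequent (cross-dataset) clusters

Each per-dataset cluster contributes all C(k, 2) probe pairs (complete
graph); within one dataset a pair is counted once even if two overlapping
clusters share it. Pairs are pooled over datasets; the count of datasets
containing each pair, divided by the number of datasets, is the edge weight
of the frequency network. This network is mined with the same parameters
except γ = 0.5 and — deliberately — **without** balancing or rescaling:
only on raw fractional weights does γ = 0.5 mean "seeded by a pair present
in at least half the datasets". Fractions rather than raw counts keep γ
scale-free in the number of datasets.

## Eigengene and downstream statistics

For a cluster in a dataset, probe rows are standardized (mean 0, sd 1,
denominator n−1; constant rows are zeroed with a warning), the thin SVD is
taken, and the eigengene is the per-sample score vector of the first
component (`s₁·v₁`), with the unit-norm first left singular vector as probe
weights and `variance_explained = s₁²/Σsᵢ²`. The sign is chosen so the
eigengene correlates non-negatively with the cluster's per-sample mean
beta: "high eigengene" reads as "more methylated". Standardizing before
the SVD follows the established module-eigengene construction from
co-expression analysis; it stops high-variance probes from dominating the
summary.

* **Tumor/normal separation**: Mann–Whitney AUC
  `P(random tumor score > random normal score)` with midrank tie handling,
  two-sided rank-sum p-value; direction `tumor_high` iff AUC ≥ 0.5.
  Requires ≥ 3 samples per group, otherwise the dataset is skipped with a
  logged reason (mirroring the exclusion of cohorts without normals). A
  rank statistic is the natural choice next to a Spearman-based network:
  both are invariant to monotone rescaling.
* **Age association**: Spearman correlation between eigengene and age,
  missing ages dropped pairwise, skipped below 10 aged samples.
* **Sorted display**: samples ordered by eigengene descending (ties by
  sample id) with group labels, for sorted-bar plots.
* **Cross-dataset comparison**: per-dataset coerced gene lists (first
  gene symbol per probe, order-preserving dedup — the first-member rule
  avoids over-counting gene families), pairwise Jaccard indices; common
  clusters between two platforms of one cancer type are pairs sharing
  ≥ 25% of genes relative to the smaller gene set (the `min` denominator
  matches the miner's overlap-ratio convention; `union` would be the
  stricter alternative); pan-cluster edge contributions are
  `100·|pan edges ∩ dataset edges|/|pan edges|`; reference gene lists
  (e.g. tumor suppressors) are crosschecked by intersection with a
  presence matrix output. Heatmap ordering uses average-linkage
  hierarchical clustering of the raw matrix; outputs are ordered tables,
  not styled figures.

## Synthetic studies

The generator emulates a panel of cohorts sharing one probe namespace.
Module probes follow

    beta_ij = invlogit(baseline_mu + tumor_shift·1[tumor_j]
                       + loading_i·f_j + ε_ij)

with `f_j ~ N(0,1)` per sample, `ε_ij ~ N(0, noise_sd)`, loadings drawn
once per module from `loading_range`. The inverse-logit keeps beta in
(0, 1) while leaving rank correlations exactly those of the latent scale.
Background probes are inverse-logit of independent normals with
probe-specific means spanning low to high methylation (U(−2.5, 2.5)) and
latent sds U(0.3, 1.0). An X-inactivation-like option draws a bimodal
factor (±1.5 ± N(0, 0.3)) and annotates the module's probes on chrX — a
positive-control module that exists regardless of disease state. A
configurable fraction of probes (default 5%) is annotated with
semicolon-joined multi-gene families to exercise the first-member mapping
rule. One global seed drives everything; per-dataset substreams are
spawned deterministically from it, so studies are bit-for-bit reproducible.

The reference study (`default_study_config`) is 6 datasets × 1,500 probes
× 120 samples with 25% normals: three shared 30-probe modules planted in
datasets 0–3 (tumor shifts +2, −2, 0 on the latent scale), two
dataset-specific 30-probe modules (datasets 4 and 5), noise sd 0.4.
Unstated knobs were fixed once on substantive grounds: the
hypomethylated-in-tumor module gets baseline_mu = +2 (a module
demethylated in tumors is one that starts heavily methylated in normals —
with a mid baseline the −2 shift drags the cohort mean under the
20th-percentile mean filter and the module ceases to exist downstream);
loadings are U(0.55, 0.75), i.e. homogeneous tight modules with
within-module |Spearman| ≈ 0.6–0.8, the regime the miner is built for —
under strongly heterogeneous loadings the decay-rate rule prunes the
weakest-loading probes from the module tail.

What the simulator does **not** model: CpG-island spatial correlation,
batch/platform effects, copy-number contamination, cell-type composition,
realistic age–methylation trends (ages are independent of all latent
factors by design, providing a null). Passing tests therefore demonstrate
correctness of the algorithms under the latent-factor model, not
robustness to those real-data phenomena.

## Numerical and degenerate-input choices

* Exact symmetry, zero diagonal and non-negativity are enforced/validated
  on every network; balancing re-symmetrizes each iterate.
* Dense matrices throughout, with a 30,000-node budget; beyond it the
  package instructs stricter filtering rather than silently sparsifying.
* Seeds compare with `≥ γ`, merges with `> β`, filters with strict `<` at
  thresholds — boundary cases are pinned by unit tests.
* Empty-vs-empty Jaccard returns 0 with a warning; empty reference lists
  crosscheck to fraction 0 with a warning.
* Beta values are clipped to [1e-6, 1−1e-6] on emission so files
  round-trip strictly inside (0, 1) at 6 decimals.

## Problem sizes

The test suite and the acceptance script run the full reference study
(6 × 1,500 × 120) end-to-end — about two seconds on one core — plus
randomized oracle comparisons (miner vs a brute-force re-enactment on
≤ 12-node networks; balancing on 100 random networks; eigengene vs an
eigendecomposition PCA oracle; filters vs a plain-Python percentile
oracle). These sizes were chosen so every claim is recomputed from scratch
on every run.

## Known limitations

* The miner's growth is greedy with no backtracking; a module whose
  weakest members fall below ~75% of the current cluster density (the
  λ=t=1 decay bound at moderate sizes) will be truncated rather than
  recovered whole.
* The frequency network treats every dataset equally; two platforms of the
  same cancer type count twice, which is intended (a larger pool) but
  means platform-duplicated cancers weigh more.
* Separation AUC and age SCC are per-dataset marginal statistics; no
  multiple-testing correction is applied across datasets × clusters in the
  summary table (the table reports raw p-values).
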