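"""SVD eigengenes and downstream per-cluster statistics.

A cluster's eigengene in one dataset is the per-sample score of the first
singular component of the row-standardized probe x sample sub-matrix — a
unit-norm weighted average of the member probes' methylation, concentrated
along the direction of highest variance.  The sign is fixed so the
eigengene correlates non-negatively with the cluster's per-sample mean
beta, i.e. a high eigengene reads as "more methylated".

Downstream statistics are rank-based, matching the Spearman-based network
construction: tumor/normal separation is the Mann-Whitney AUC
(P(random tumor score > random normal score), tie-corrected) with a
rank-sum p-value, and the age association is a Spearman correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DataError
from .io import BetaMatrix, SampleSheet

logger = logging.getLogger("panmethyl")


@dataclass
class Eigengene:
    cluster_id: str
    dataset: str
    sample_ids: list[str]
    values: np.ndarray          # one score per sample
    probe_ids: list[str]        # cluster probes actually used
    probe_weights: np.ndarray   # unit-norm loading vector over probe_ids
    variance_explained: float

    def __post_init__(self):
        if abs(np.linalg.norm(self.probe_weights) - 1.0) > 1e-9:
            raise DataError("Eigengene: probe_weights must have unit norm")
        if len(self.values) != len(self.sample_ids):
            raise DataError("Eigengene: values length != sample count")


@dataclass(frozen=True)
class SeparationResult:
    auc: float
    direction: str  # "tumor_high" | "normal_high"
    p_value: float
    n_tumor: int
    n_normal: int


@dataclass(frozen=True)
class AgeCorrelation:
    scc: float
    p_value: float
    n_used: int


def compute_eigengene(
    bm: BetaMatrix,
    cluster_probes,
    cluster_id: str = "",
    dataset: str = "",
) -> Eigengene:
    """First-singular-component summary of a cluster's methylation.

    Cluster probes absent from ``bm`` are dropped with a warning; fewer
    than 2 present probes (or fewer than 3 samples) is an error.  Probe
    rows are standardized to mean 0, sd 1 before the SVD; constant rows are
    zeroed out with a warning.
    """
    index = bm.probe_index()
    present = [p for p in cluster_probes if p in index]
    missing = [p for p in cluster_probes if p not in index]
    if missing:
        logger.warning(
            "compute_eigengene[%s/%s]: %d cluster probes not in matrix",
            dataset, cluster_id, len(missing),
        )
    if len(present) < 2:
        raise DataError(
            f"compute_eigengene: fewer than 2 cluster probes present; "
            f"missing: {missing[:10]}"
        )
    if bm.n_samples < 3:
        raise DataError(f"compute_eigengene: need >= 3 samples, got {bm.n_samples}")

    X = bm.values[[index[p] for p in present]]
    if np.isnan(X).any():
        raise DataError("compute_eigengene: missing values present")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("compute_eigengene: %d constant probes zeroed", int(constant.sum()))
        sd[constant] = 1.0
    Z = (X - mu) / sd
    Z[constant] = 0.0
    if not np.any(Z):
        raise DataError("compute_eigengene: all cluster probes constant")

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = s[0] * Vt[0]
    weights = U[:, 0]
    mean_beta = X.mean(axis=0)
    if np.std(scores) > 0 and np.std(mean_beta) > 0:
        if np.corrcoef(scores, mean_beta)[0, 1] < 0:
            scores = -scores
            weights = -weights
    variance_explained = float(s[0] ** 2 / np.sum(s**2))
    return Eigengene(
        cluster_id=cluster_id,
        dataset=dataset,
        sample_ids=list(bm.sample_ids),
        values=scores,
        probe_ids=present,
        probe_weights=weights / np.linalg.norm(weights),
        variance_explained=variance_explained,
    )


def centralize_beta(bm: BetaMatrix, cluster_probes) -> np.ndarray:
    """Each present cluster probe's row minus its own mean (row means -> 0)."""
    index = bm.probe_index()
    present = [p for p in cluster_probes if p in index]
    if not present:
        raise DataError("centralize_beta: no cluster probes present")
    X = bm.values[[index[p] for p in present]]
    return X - X.mean(axis=1, keepdims=True)


def separation_statistic(
    eg: Eigengene,
    sheet: SampleSheet,
    min_per_group: int = 3,
) -> SeparationResult | None:
    """Rank-based tumor/normal separation of the eigengene.

    AUC = P(random tumor score > random normal score), tie-corrected
    (Mann-Whitney U over n_tumor * n_normal); p from the two-sided rank-sum
    null.  Returns None (with a logged reason) when either group has fewer
    than ``min_per_group`` samples.
    """
    aligned = sheet.aligned_to(eg.sample_ids)
    tumor = aligned.group_values(eg.values, "tumor")
    normal = aligned.group_values(eg.values, "normal")
    if min(len(tumor), len(normal)) < min_per_group:
        logger.info(
            "separation_statistic[%s/%s]: skipped (%d tumor, %d normal < %d per group)",
            eg.dataset, eg.cluster_id, len(tumor), len(normal), min_per_group,
        )
        return None
    res = stats.mannwhitneyu(tumor, normal, alternative="two-sided")
    auc = float(res.statistic) / (len(tumor) * len(normal))
    direction = "tumor_high" if auc >= 0.5 else "normal_high"
    return SeparationResult(auc, direction, float(res.pvalue), len(tumor), len(normal))


def sort_samples_by_eigengene(
    eg: Eigengene, sheet: SampleSheet
) -> list[tuple[str, str]]:
    """(sample_id, group) pairs ordered by eigengene value, high to low;
    ties by sample id."""
    aligned = sheet.aligned_to(eg.sample_ids)
    rows = list(zip(eg.sample_ids, aligned.groups, eg.values))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return [(sid, grp) for sid, grp, _ in rows]


def age_correlation(
    eg: Eigengene,
    sheet: SampleSheet,
    min_n: int = 10,
) -> AgeCorrelation | None:
    """Spearman correlation between eigengene scores and age.

    Samples with missing age are dropped pairwise; fewer than ``min_n``
    aged samples returns None with a logged reason.
    """
    aligned = sheet.aligned_to(eg.sample_ids)
    mask = ~np.isnan(aligned.ages)
    n_used = int(mask.sum())
    if n_used < min_n:
        logger.info(
            "age_correlation[%s/%s]: skipped (%d aged samples < %d)",
            eg.dataset, eg.cluster_id, n_used, min_n,
        )
        return None
    scc, p = stats.spearmanr(eg.values[mask], aligned.ages[mask])
    return AgeCorrelation(float(scc), float(p), n_used)
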