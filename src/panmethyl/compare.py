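"""Cluster comparison across cancer types, platforms and reference gene lists."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .exceptions import DataError
from .io import ProbeAnnotation
from .lmqcm import Cluster
from .preprocess import map_probes_to_genes

logger = logging.getLogger("panmethyl")


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of unique gene symbols (order of first occurrence kept)."""

    label: str
    genes: tuple[str, ...]

    def __post_init__(self):
        seen = set()
        deduped = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        object.__setattr__(self, "genes", tuple(deduped))

    @property
    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def _to_set(x) -> frozenset[str]:
    return x.as_set if isinstance(x, GeneSet) else frozenset(x)


def jaccard_index(a, b) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty (logged)."""
    sa, sb = _to_set(a), _to_set(b)
    union = sa | sb
    if not union:
        logger.warning("jaccard_index: both gene sets empty, returning 0 by convention")
        return 0.0
    return len(sa & sb) / len(union)


@dataclass(frozen=True)
class CommonClusterReport:
    """Common clusters between two platforms of the same cancer type.

    ``pairs`` holds (index in platform 1, index in platform 2, shared
    genes); the counts mirror the "clusters from platform 1 / clusters from
    platform 2 / common pairs" bookkeeping.
    """

    pairs: tuple[tuple[int, int, tuple[str, ...]], ...]
    n_clusters_1: int
    n_clusters_2: int
    n_pairs: int
    common_genes: tuple[str, ...]


def find_common_platform_clusters(
    clusters_a: list[Cluster],
    clusters_b: list[Cluster],
    annotation: ProbeAnnotation,
    threshold: float = 0.25,
) -> CommonClusterReport:
    """Pair clusters from two platforms sharing >= ``threshold`` of genes.

    Clusters are gene-mapped first; a pair is common when
    |shared genes| / min(gene-set sizes) >= threshold (the "25% or more"
    rule).  One cluster may appear in several pairs; it still counts once
    toward its platform's cluster tally.  Shared genes of all common pairs
    are pooled into ``common_genes``.
    """
    genes_a = [map_probes_to_genes(c.probe_ids, annotation) for c in clusters_a]
    genes_b = [map_probes_to_genes(c.probe_ids, annotation) for c in clusters_b]
    pairs = []
    pooled: list[str] = []
    pooled_seen: set[str] = set()
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            if not ga or not gb:
                continue
            shared = sorted(set(ga) & set(gb))
            if len(shared) / min(len(ga), len(gb)) >= threshold:
                pairs.append((i, j, tuple(shared)))
                for g in shared:
                    if g not in pooled_seen:
                        pooled_seen.add(g)
                        pooled.append(g)
    used_a = {i for i, _j, _s in pairs}
    used_b = {j for _i, j, _s in pairs}
    return CommonClusterReport(
        tuple(pairs), len(used_a), len(used_b), len(pairs), tuple(pooled)
    )


def edge_contribution(pan_cluster: Cluster, dataset_edge_set: set) -> float:
    """Percentage of the pan-cluster's complete-graph edges found in a
    dataset's pooled cluster edges."""
    ids = sorted(pan_cluster.probe_ids)
    if len(ids) < 2:
        raise DataError("edge_contribution: pan cluster has no edges")
    pan_edges = {
        (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
    }
    return 100.0 * len(pan_edges & dataset_edge_set) / len(pan_edges)


@dataclass(frozen=True)
class CrosscheckResult:
    hits: tuple[str, ...]
    hit_fraction: float


def crosscheck_gene_lists(cluster_genes, reference) -> CrosscheckResult:
    """Intersection with a reference list (e.g. tumor suppressors) and the
    fraction of the reference covered.  Empty reference -> fraction 0 with
    a warning."""
    cset, rset = _to_set(cluster_genes), _to_set(reference)
    hits = tuple(sorted(cset & rset))
    if not rset:
        logger.warning("crosscheck_gene_lists: empty reference list, fraction set to 0")
        return CrosscheckResult(hits, 0.0)
    return CrosscheckResult(hits, len(hits) / len(rset))


def crosscheck_presence_matrix(
    gene_sets: dict[str, GeneSet], reference
) -> pd.DataFrame:
    """Reference gene x dataset matrix of 'X' marks (hit) / '' (miss)."""
    rset = sorted(_to_set(reference))
    data = {
        label: ["X" if g in gs.as_set else "" for g in rset]
        for label, gs in gene_sets.items()
    }
    return pd.DataFrame(data, index=rset)


def jaccard_matrix(gene_sets: list[GeneSet]) -> pd.DataFrame:
    """Square Jaccard-index matrix over labelled gene sets."""
    labels = [gs.label for gs in gene_sets]
    data = [[jaccard_index(a, b) for b in gene_sets] for a in gene_sets]
    return pd.DataFrame(data, index=labels, columns=labels)


def average_linkage_order(matrix: pd.DataFrame) -> list[str]:
    """Leaf order of average-linkage hierarchical clustering of a square
    similarity matrix (used to dump ordered heatmap tables)."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    if matrix.shape[0] < 3:
        return list(matrix.index)
    sim = matrix.to_numpy()
    dist = sim.max() - sim
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    order = leaves_list(average(condensed))
    return [matrix.index[i] for i in order]
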