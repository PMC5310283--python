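"""Cross-dataset edge pooling and frequent (pan-cancer) cluster mining.

Every per-dataset cluster is expanded to its complete graph of probe pairs;
the pooled pairs are tallied across datasets, and the tally, expressed as a
fraction of datasets, becomes the edge weight of a new network.  Mining
that network with gamma = 0.5 guarantees every frequent cluster is seeded
by a pair that co-occurred in at least half of the datasets.  The frequency
network is deliberately *not* weight-balanced: the fraction-of-datasets
interpretation of gamma only holds on raw fractional weights.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DataError
from .lmqcm import Cluster, MinerParams, MiningTrace, merge_clusters, mine_clusters
from .network import WeightedNetwork

Pair = tuple[str, str]


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a < b else (b, a)


@dataclass
class EdgeFrequencyTable:
    """Unordered probe pair -> number of datasets containing the pair."""

    entries: dict[Pair, int]
    n_datasets: int

    def __post_init__(self):
        for pair, count in self.entries.items():
            if not (1 <= count <= self.n_datasets):
                raise DataError(
                    f"EdgeFrequencyTable: count {count} for {pair} outside "
                    f"[1, {self.n_datasets}]"
                )

    def fraction(self, pair: Pair) -> float:
        return self.entries[pair] / self.n_datasets

    def histogram(self) -> dict[int, int]:
        """count value -> number of distinct pairs with that count."""
        hist = Counter(self.entries.values())
        return dict(sorted(hist.items()))


def clusters_to_edges(clusters: list[Cluster]) -> set[Pair]:
    """Union of complete-graph probe pairs over one dataset's clusters.

    A pair shared by overlapping clusters is counted once (set semantics).
    """
    edges: set[Pair] = set()
    for c in clusters:
        ids = c.probe_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                edges.add(_pair(ids[i], ids[j]))
    return edges


def tally_edge_frequencies(per_dataset_edge_sets: list[set[Pair]]) -> EdgeFrequencyTable:
    """Count, for each pooled pair, the number of datasets containing it."""
    if len(per_dataset_edge_sets) < 2:
        raise DataError("tally_edge_frequencies: need at least 2 datasets")
    counts: Counter[Pair] = Counter()
    for edges in per_dataset_edge_sets:
        counts.update(edges)
    return EdgeFrequencyTable(dict(counts), len(per_dataset_edge_sets))


def build_frequency_network(tab: EdgeFrequencyTable) -> WeightedNetwork:
    """Network weighted by the fraction of datasets containing each pair."""
    if not tab.entries:
        raise DataError("build_frequency_network: empty frequency table")
    nodes = sorted({p for pair in tab.entries for p in pair})
    idx = {p: i for i, p in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for (a, b), count in tab.entries.items():
        w = count / tab.n_datasets
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    return WeightedNetwork(nodes, W, meta={"n_datasets": tab.n_datasets})


def mine_frequent_clusters(
    freq_net: WeightedNetwork,
    params: MinerParams | None = None,
    trace: MiningTrace | None = None,
) -> list[Cluster]:
    """Mine + merge frequent clusters on the raw fractional-weight network.

    Defaults to the step-1 miner settings with gamma = 0.5.  Each returned
    cluster contains at least one pair present in >= half the datasets (its
    seed edge).
    """
    params = params or MinerParams(gamma=0.5)
    mined = mine_clusters(freq_net, params, source="pooled", trace=trace)
    merged = merge_clusters(mined, params.beta, net=freq_net)
    return [c for c in merged if c.size >= params.min_size]


# ---------------------------------------------------------------------------
# serialization


def write_frequency_table(tab: EdgeFrequencyTable, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_a\tprobe_b\tcount\tfraction\n")
        for (a, b), count in sorted(tab.entries.items()):
            fh.write(f"{a}\t{b}\t{count}\t{count / tab.n_datasets:.6g}\n")
    return path


def read_frequency_table(path, n_datasets: int | None = None) -> EdgeFrequencyTable:
    entries: dict[Pair, int] = {}
    max_count = 0
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("probe_a"):
            raise DataError(f"{path}: malformed frequency table header")
        for line in fh:
            a, b, count, frac = line.rstrip("\n").split("\t")
            count = int(count)
            entries[_pair(a, b)] = count
            max_count = max(max_count, count)
            if n_datasets is None and float(frac) > 0:
                n_datasets = round(count / float(frac))
    if n_datasets is None:
        raise DataError(f"{path}: cannot infer dataset count from empty table")
    return EdgeFrequencyTable(entries, n_datasets)
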