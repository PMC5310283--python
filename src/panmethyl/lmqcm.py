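"""Greedy quasi-clique module mining (lmQCM) with overlap-based merging.

The miner works on any :class:`~panmethyl.network.WeightedNetwork`:

1. sort all edges by weight, descending;
2. seed a new cluster from the heaviest remaining *eligible* edge of weight
   >= gamma (an edge is ineligible once both endpoints already co-occur in
   an identified cluster);
3. grow the cluster greedily: at each step the outside vertex with maximal
   total weight to the current members is the candidate, and it is accepted
   only if the resulting density satisfies
   ``d_new >= alpha_n * max(gamma, d_current)`` with
   ``alpha_n = 1 - 1/(2*lambda*(n + t))`` at the current cluster size ``n``
   — lambda and t control the allowed per-step decreasing rate of the
   density, and because ``alpha_n * max(gamma, d) >= gamma * alpha_n`` every
   accepted step also clears the absolute floor :func:`density_floor`;
4. when no seed edge of weight >= gamma remains, drop clusters below the
   minimum size and merge clusters whose overlap ratio (intersection over
   the smaller cluster) exceeds beta, iterating merges to a fixed point.

All tie-breaks (equal edge weights, equal candidate gains, equal sizes
during merging) are lexicographic by probe id, so the output is a
deterministic function of the network and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .network import WeightedNetwork


@dataclass(frozen=True)
class MinerParams:
    """lmQCM parameters.

    gamma    -- minimum weight of a cluster-seeding edge;
    lam, t   -- decay controls of the adaptive density floor (both >= 1);
    beta     -- maximum allowed overlap ratio between two clusters, in (0, 1];
    min_size -- smallest cluster retained for merging (default 20).
    """

    gamma: float = 0.6
    lam: float = 1.0
    t: float = 1.0
    beta: float = 0.4
    min_size: int = 20

    def __post_init__(self):
        if self.gamma <= 0:
            raise DataError("MinerParams: gamma must be > 0")
        if self.lam < 1 or self.t < 1:
            raise DataError("MinerParams: lambda and t must be >= 1")
        if not (0 < self.beta <= 1):
            raise DataError("MinerParams: beta must be in (0, 1]")
        if self.min_size < 2:
            raise DataError("MinerParams: min_size must be >= 2")


@dataclass(frozen=True)
class Cluster:
    """An ordered set of probe ids mined from one network."""

    probe_ids: tuple[str, ...]
    source_dataset: str = ""
    density: float = math.nan

    def __post_init__(self):
        if len(self.probe_ids) < 2:
            raise DataError("Cluster: needs at least 2 probes")

    @property
    def size(self) -> int:
        return len(self.probe_ids)

    @property
    def probe_set(self) -> frozenset[str]:
        return frozenset(self.probe_ids)


@dataclass
class GrowthStep:
    """One accepted vertex addition, recorded when mining with a trace."""

    cluster_index: int
    size_before: int
    added: str
    density_after: float
    floor: float


@dataclass
class MiningTrace:
    """Audit trail of seeds and growth steps for one mining run."""

    seeds: list[tuple[str, str, float]] = field(default_factory=list)
    steps: list[GrowthStep] = field(default_factory=list)


def density(net: WeightedNetwork, members) -> float:
    """Weighted subgraph density: sum of within-set weights over C(k, 2)."""
    idx = net.node_index()
    try:
        rows = [idx[m] for m in members]
    except KeyError as e:
        raise DataError(f"density: unknown node {e.args[0]!r}") from None
    k = len(rows)
    if k < 2:
        raise DataError(f"density: need at least 2 members, got {k}")
    sub = net.weights[np.ix_(rows, rows)]
    return float(sub.sum() / 2.0 / (k * (k - 1) / 2.0))


def density_floor(n: int, params: MinerParams) -> float:
    """Adaptive lower bound on cluster density at current size ``n``.

    ``gamma * (1 - 1/(2*lambda*(n + t)))`` -- strictly increasing in ``n``
    with asymptote gamma, so larger clusters must stay denser relative to
    the seed threshold while small clusters get slack.
    """
    return params.gamma * (1.0 - 1.0 / (2.0 * params.lam * (n + params.t)))


def _grow(W: np.ndarray, ids: np.ndarray, i: int, j: int, params: MinerParams,
          trace: MiningTrace | None, cluster_index: int) -> list[int]:
    """Greedy expansion from seed edge (i, j); returns member indices in
    order of addition."""
    n = W.shape[0]
    members = [i, j]
    inset = np.zeros(n, dtype=bool)
    inset[i] = inset[j] = True
    totw = W[:, i] + W[:, j]
    internal = W[i, j]
    while len(members) < n:
        k = len(members)
        cand = np.where(inset, -np.inf, totw)
        best_w = cand.max()
        ties = np.flatnonzero(cand == best_w)
        best = ties[np.argmin(ids[ties])] if ties.size > 1 else int(ties[0])
        new_density = (internal + totw[best]) / (k * (k + 1) / 2.0)
        current_density = internal / (k * (k - 1) / 2.0)
        alpha = 1.0 - 1.0 / (2.0 * params.lam * (k + params.t))
        floor = density_floor(k, params)  # == alpha * gamma
        if new_density < alpha * max(params.gamma, current_density):
            break
        internal += totw[best]
        inset[best] = True
        members.append(int(best))
        totw = totw + W[:, best]
        if trace is not None:
            trace.steps.append(
                GrowthStep(cluster_index, k, str(ids[best]), float(new_density), floor)
            )
    return members


def mine_clusters(
    net: WeightedNetwork,
    params: MinerParams | None = None,
    source: str = "",
    trace: MiningTrace | None = None,
) -> list[Cluster]:
    """Mine clusters from a weighted network (no merging; see
    :func:`merge_clusters`).

    Returns clusters of size >= ``params.min_size`` in mining order.  Probe
    ids inside each cluster appear in order of addition (seed endpoints
    first).  The run is deterministic: ties are broken lexicographically.
    """
    params = params or MinerParams()
    n = net.n_nodes
    if n == 0:
        return []
    ids = np.asarray(net.node_ids, dtype=object)
    W = net.weights
    iu, ju = np.triu_indices(n, 1)
    w = W[iu, ju]
    sel = w >= params.gamma
    if not sel.any():
        return []
    iu, ju, w = iu[sel], ju[sel], w[sel]
    lo = np.minimum(ids[iu], ids[ju])
    hi = np.maximum(ids[iu], ids[ju])
    order = np.lexsort((hi, lo, -w))

    grown: list[list[int]] = []
    membership: dict[int, set[int]] = {}
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        mi = membership.get(i)
        mj = membership.get(j)
        if mi and mj and (mi & mj):
            continue  # both endpoints already co-occur in an identified cluster
        if trace is not None:
            a, b = sorted((str(ids[i]), str(ids[j])))
            trace.seeds.append((a, b, float(w[e])))
        members = _grow(W, ids, i, j, params, trace, len(grown))
        ci = len(grown)
        grown.append(members)
        for v in members:
            membership.setdefault(v, set()).add(ci)

    out = []
    for members in grown:
        if len(members) >= params.min_size:
            probe_ids = tuple(str(ids[v]) for v in members)
            out.append(
                Cluster(probe_ids, source_dataset=source, density=density(net, probe_ids))
            )
    return out


def overlap_ratio(a, b) -> float:
    """|intersection| over the size of the smaller cluster."""
    sa = a.probe_set if isinstance(a, Cluster) else frozenset(a)
    sb = b.probe_set if isinstance(b, Cluster) else frozenset(b)
    if not sa or not sb:
        raise DataError("overlap_ratio: empty cluster")
    return len(sa & sb) / min(len(sa), len(sb))


def merge_clusters(
    clusters: list[Cluster],
    beta: float,
    net: WeightedNetwork | None = None,
) -> list[Cluster]:
    """Merge clusters with overlap ratio strictly greater than beta.

    Pairs are scanned in descending-size order (ties lexicographic); each
    merge replaces the pair with the union of their probe sets and the scan
    restarts, so the result is a fixed point with all pairwise overlap
    ratios <= beta.  Densities are recomputed from ``net`` when given.
    Output is sorted by size descending.
    """

    def sort_key(c: Cluster):
        return (-c.size, tuple(sorted(c.probe_ids)))

    work = sorted(clusters, key=sort_key)
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                if overlap_ratio(work[i], work[j]) > beta:
                    union = tuple(sorted(work[i].probe_set | work[j].probe_set))
                    merged = Cluster(
                        union,
                        source_dataset=work[i].source_dataset,
                        density=density(net, union) if net is not None else math.nan,
                    )
                    work = [c for k, c in enumerate(work) if k not in (i, j)]
                    work.append(merged)
                    work.sort(key=sort_key)
                    changed = True
                    break
            if changed:
                break
    return work


# ---------------------------------------------------------------------------
# serialization


def write_clusters(clusters: list[Cluster], path) -> None:
    """TSV: ``cluster_id  size  density  probe_ids`` (comma-joined)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster_id\tsize\tdensity\tprobe_ids\n")
        for k, c in enumerate(clusters, start=1):
            dens = "" if math.isnan(c.density) else f"{c.density:.6g}"
            fh.write(f"C{k}\t{c.size}\t{dens}\t{','.join(c.probe_ids)}\n")


def write_clusters_gmt(clusters: list[Cluster], path) -> None:
    """GMT-style lines: ``cluster_id <tab> source <tab> probe...``."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, c in enumerate(clusters, start=1):
            fields = [f"C{k}", c.source_dataset or "-", *c.probe_ids]
            fh.write("\t".join(fields) + "\n")


def read_clusters(path, source: str = "") -> list[Cluster]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("cluster_id"):
            raise DataError(f"{path}: malformed cluster file header")
        for line in fh:
            _cid, _size, dens, probes = line.rstrip("\n").split("\t")
            out.append(
                Cluster(
                    tuple(probes.split(",")),
                    source_dataset=source,
                    density=float(dens) if dens else math.nan,
                )
            )
    return out
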