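"""Weighted co-methylation networks.

The co-methylation network over probes has edge weight
``|Spearman rank correlation|`` of the two probes' beta values across all
samples of a dataset (tumor and normal pooled).  Before module mining the
weight matrix is balanced by the iterated symmetric scaling
``W <- D^{-1/2} W D^{-1/2}`` (Sinkhorn-Knopp on a symmetric matrix, the same
iteration used to normalize the graph Laplacian in spectral clustering)
until all row sums are 1 within tolerance.  Balancing removes the bias of
the greedy miner toward hub-dominated dense regions; a final rescale to
unit maximum weight restores an absolute scale on which the seed threshold
gamma is meaningful.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .exceptions import ConvergenceError, DataError
from .io import BetaMatrix

logger = logging.getLogger("panmethyl")

#: refuse dense networks above this node count; stricter probe filtering is
#: the intended remedy, not sparsification
MAX_DENSE_NODES = 30_000


@dataclass
class WeightedNetwork:
    """Symmetric non-negative edge weights over probes, zero diagonal."""

    node_ids: list[str]
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise DataError(f"weights shape {self.weights.shape} != ({n}, {n})")
        if n > MAX_DENSE_NODES:
            raise DataError(
                f"{n} nodes exceeds the dense-network budget ({MAX_DENSE_NODES}); "
                "filter probes more strictly"
            )
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise DataError("weight matrix is not symmetric")
        if np.any(self.weights < 0):
            raise DataError("negative edge weight")
        if np.any(np.diagonal(self.weights) != 0):
            raise DataError("non-zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def node_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.node_ids)}

    def weight_between(self, a: str, b: str) -> float:
        idx = self.node_index()
        return float(self.weights[idx[a], idx[b]])


def build_scc_network(bm: BetaMatrix) -> WeightedNetwork:
    """|Spearman| correlation network over the probes of a beta matrix.

    Ties are handled with average ranks.  Probes that are constant across
    samples get weight 0 to every other probe.  Requires at least 3 samples
    and no missing values.
    """
    if bm.n_samples < 3:
        raise DataError(f"build_scc_network: need >= 3 samples, got {bm.n_samples}")
    if np.isnan(bm.values).any():
        raise DataError("build_scc_network: missing values present; filter probes first")

    ranks = np.apply_along_axis(rankdata, 1, bm.values)
    sd = ranks.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr = np.nan_to_num(corr, nan=0.0)
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    W = np.abs(corr)
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(list(bm.probe_ids), W)


def normalize_weights(
    net: WeightedNetwork,
    tol: float = 1e-4,
    max_iter: int = 100,
    inspect=None,
) -> WeightedNetwork:
    """Iterate ``W <- D^{-1/2} W D^{-1/2}`` until ``max |row sum - 1| <= tol``.

    Zero-degree nodes are removed first (with a warning).  Symmetry, the
    zero diagonal and non-negativity are preserved at every iterate; if the
    residual does not reach ``tol`` within ``max_iter`` iterations a
    :class:`ConvergenceError` carrying the final residual is raised.

    ``inspect``, if given, is called with the weight matrix after every
    iteration (used by the test suite to audit the per-iterate invariants).
    """
    W = net.weights.copy()
    degree = W.sum(axis=1)
    keep = degree > 0
    ids = list(net.node_ids)
    if not keep.all():
        dropped = [p for p, k in zip(ids, keep) if not k]
        logger.warning("normalize_weights: removing %d zero-degree nodes", len(dropped))
        W = W[np.ix_(keep, keep)]
        ids = [p for p, k in zip(ids, keep) if k]
        if not ids:
            raise DataError("normalize_weights: no nodes with positive degree")

    iterations = 0
    residual = float(np.abs(W.sum(axis=1) - 1.0).max())
    while residual > tol and iterations < max_iter:
        d = W.sum(axis=1)
        scale = 1.0 / np.sqrt(d)
        W = W * np.outer(scale, scale)
        W = (W + W.T) / 2.0  # keep symmetry exact against float drift
        iterations += 1
        residual = float(np.abs(W.sum(axis=1) - 1.0).max())
        if inspect is not None:
            inspect(W)
    if residual > tol:
        raise ConvergenceError(
            f"normalize_weights: residual {residual:.3e} > tol {tol:g} "
            f"after {max_iter} iterations",
            residual=residual,
        )
    return WeightedNetwork(ids, W, meta={"tol": tol, "iterations": iterations})


def rescale_unit_max(net: WeightedNetwork) -> WeightedNetwork:
    """Divide all weights by the maximum weight so the heaviest edge is 1.

    Applied after balancing, before mining, so that the seed threshold gamma
    reads as a fraction of the strongest (balanced) association in the
    network rather than an absolute doubly-stochastic weight.
    """
    wmax = float(net.weights.max())
    if wmax <= 0:
        raise DataError("rescale_unit_max: network has no positive weight")
    return WeightedNetwork(
        list(net.node_ids), net.weights / wmax, meta={**net.meta, "max_weight": wmax}
    )


# ---------------------------------------------------------------------------
# serialization: edge-list TSV + JSON sidecar


def write_network(net: WeightedNetwork, path, min_weight: float = 0.0) -> Path:
    """Write ``probe_a  probe_b  weight`` (pairs lexicographic, a < b)."""
    path = Path(path)
    rows = []
    n = net.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            w = net.weights[i, j]
            if w > min_weight or (w == min_weight and min_weight == 0.0 and w > 0):
                a, b = sorted((net.node_ids[i], net.node_ids[j]))
                rows.append((a, b, w))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_a\tprobe_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")
    sidecar = {"n_nodes": net.n_nodes, **net.meta}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_network(path) -> WeightedNetwork:
    path = Path(path)
    nodes: dict[str, int] = {}
    edges: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("probe_a"):
            raise DataError(f"{path}: malformed network header")
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            edges.append((a, b, float(w)))
            for x in (a, b):
                if x not in nodes:
                    nodes[x] = len(nodes)
    ids = sorted(nodes)
    idx = {p: i for i, p in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for a, b, w in edges:
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    return WeightedNetwork(ids, W)
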