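"""Greedy quasi-clique miner: density arithmetic, growth rule, merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmethyl.exceptions import DataError
from panmethyl.lmqcm import (
    Cluster,
    MinerParams,
    MiningTrace,
    density,
    density_floor,
    merge_clusters,
    mine_clusters,
    overlap_ratio,
    read_clusters,
    write_clusters,
)
from panmethyl.network import WeightedNetwork

from .oracles import simulate_miner, subgraph_density


def _net(weight_map, nodes=None):
    """Build a network from {frozenset({a, b}): w}."""
    if nodes is None:
        nodes = sorted({x for pair in weight_map for x in pair})
    idx = {p: i for i, p in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for pair, w in weight_map.items():
        a, b = tuple(pair)
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    return WeightedNetwork(list(nodes), W)


def _clique(nodes, w):
    return {
        frozenset((a, b)): w
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    }


# ---------------------------------------------------------------------------
# density and floor


def test_density_examples_and_oracle():
    net = _net({frozenset("ab"): 1.0, frozenset("bc"): 1.0, frozenset("ac"): 0.0})
    assert density(net, ["a", "b", "c"]) == pytest.approx(2 / 3)
    full = _net(_clique(list("abcd"), 1.0))
    assert density(full, list("abcd")) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    wmap = {
        frozenset((f"n{i}", f"n{j}")): float(rng.uniform())
        for i in range(8)
        for j in range(i + 1, 8)
    }
    net = _net(wmap)
    members = [f"n{i}" for i in (0, 2, 3, 6)]
    assert density(net, members) == pytest.approx(subgraph_density(wmap, members))
    with pytest.raises(DataError):
        density(net, ["n0"])


def test_density_floor_value_monotonicity_and_limit():
    p = MinerParams(gamma=0.6, lam=1.0, t=1.0)
    assert density_floor(20, p) == pytest.approx(0.6 * (1 - 1 / 42))
    floors = [density_floor(n, p) for n in range(2, 60)]
    assert all(b > a for a, b in zip(floors, floors[1:]))
    assert all(f < 0.6 for f in floors)
    relaxed = MinerParams(gamma=0.6, lam=1e9, t=1.0)
    assert density_floor(2, relaxed) == pytest.approx(0.6, abs=1e-8)


# ---------------------------------------------------------------------------
# overlap and merging


def test_overlap_ratio_printed_definition():
    a = Cluster(tuple(f"p{i}" for i in range(1, 11)))
    b = Cluster(tuple(f"p{i}" for i in range(6, 21)))
    assert overlap_ratio(a, b) == pytest.approx(0.5)
    assert overlap_ratio(a, Cluster(a.probe_ids + ("extra",))) == 1.0
    assert overlap_ratio(a, Cluster(("x", "y"))) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(0, 30), min_size=2, max_size=15),
    st.sets(st.integers(0, 30), min_size=2, max_size=15),
)
def test_overlap_ratio_bounds_and_symmetry(sa, sb):
    a = Cluster(tuple(f"p{x}" for x in sorted(sa)))
    b = Cluster(tuple(f"p{x}" for x in sorted(sb)))
    r = overlap_ratio(a, b)
    assert 0.0 <= r <= 1.0
    assert r == overlap_ratio(b, a)


def test_merge_strictly_greater_than_beta():
    a = Cluster(tuple(f"p{i}" for i in range(10)))
    b = Cluster(tuple(f"p{i}" for i in range(5, 15)))  # ratio 0.5
    merged = merge_clusters([a, b], beta=0.4)
    assert len(merged) == 1
    assert merged[0].probe_set == a.probe_set | b.probe_set

    c = Cluster(tuple(f"p{i}" for i in range(11, 21)))  # ratio vs b: 4/10 = 0.4
    kept = merge_clusters([b, c], beta=0.4)
    assert len(kept) == 2  # 0.4 is NOT higher than beta


def test_merge_beta_one_keeps_everything_not_nested():
    a = Cluster(("a", "b", "c"))
    b = Cluster(("b", "c", "d"))
    assert len(merge_clusters([a, b], beta=1.0)) == 2


def test_merge_iterates_to_fixed_point():
    a = Cluster(tuple(f"p{i}" for i in range(8)))
    b = Cluster(tuple(f"p{i}" for i in range(4, 12)))
    c = Cluster(tuple(f"p{i}" for i in range(8, 16)))
    merged = merge_clusters([a, b, c], beta=0.4)
    assert len(merged) == 1  # a+b union then overlaps c enough to cascade
    for x, y in [(x, y) for x in merged for y in merged if x is not y]:
        assert overlap_ratio(x, y) <= 0.4


# ---------------------------------------------------------------------------
# mining


def test_two_planted_cliques_recovered_exactly():
    nodes_a = [f"a{i:02d}" for i in range(25)]
    nodes_b = [f"b{i:02d}" for i in range(25)]
    wmap = {**_clique(nodes_a, 0.9), **_clique(nodes_b, 0.9)}
    rng = np.random.default_rng(5)
    for a in nodes_a:
        for b in nodes_b:
            wmap[frozenset((a, b))] = 0.05
    net = _net(wmap)
    clusters = mine_clusters(net, MinerParams(gamma=0.6, min_size=20))
    assert len(clusters) == 2
    assert {frozenset(c.probe_ids) for c in clusters} == {
        frozenset(nodes_a),
        frozenset(nodes_b),
    }
    assert clusters[0].density == pytest.approx(0.9)


def test_no_edge_at_gamma_means_no_clusters():
    net = _net(_clique([f"n{i}" for i in range(6)], 0.55))
    assert mine_clusters(net, MinerParams(gamma=0.6, min_size=2)) == []


def test_mining_is_deterministic():
    rng = np.random.default_rng(9)
    wmap = {
        frozenset((f"n{i:02d}", f"n{j:02d}")): float(rng.integers(1, 64)) / 64.0
        for i in range(15)
        for j in range(i + 1, 15)
    }
    net = _net(wmap)
    params = MinerParams(gamma=0.5, min_size=3)
    first = mine_clusters(net, params)
    second = mine_clusters(net, params)
    assert [c.probe_ids for c in first] == [c.probe_ids for c in second]


@pytest.mark.parametrize("seed", range(12))
def test_miner_matches_independent_simulator(seed):
    """On exhaustively checkable networks the miner reproduces the
    independently coded seed/grow/merge simulation, including ties
    (dyadic weights make float sums exact in both code paths)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 13))
    nodes = [f"n{i:02d}" for i in range(n)]
    wmap = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.85:
                wmap[frozenset((nodes[i], nodes[j]))] = float(rng.integers(1, 65)) / 64.0
    if not wmap:
        return
    params = MinerParams(gamma=0.5, lam=1.0, t=1.0, beta=0.5, min_size=2)
    net = _net(wmap, nodes=nodes)
    mined = mine_clusters(net, params)
    merged = merge_clusters(mined, params.beta, net=net)
    merged = [c for c in merged if c.size >= params.min_size]
    expected = simulate_miner(nodes, wmap, 0.5, 1.0, 1.0, 0.5, 2)
    assert [sorted(c.probe_ids) for c in merged] == [sorted(c) for c in expected]


def test_trace_records_floor_compliance():
    rng = np.random.default_rng(3)
    n = 40
    W = rng.uniform(0, 1, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    net = WeightedNetwork([f"n{i:02d}" for i in range(n)], W)
    trace = MiningTrace()
    params = MinerParams(gamma=0.6, min_size=3)
    mine_clusters(net, params, trace=trace)
    assert trace.seeds, "expected at least one seed on a dense random network"
    for step in trace.steps:
        assert step.density_after >= step.floor
        assert step.floor == pytest.approx(density_floor(step.size_before, params))


def test_cluster_serialization_roundtrip(tmp_path):
    clusters = [
        Cluster(("b", "a", "c"), source_dataset="D1", density=0.75),
        Cluster(("x", "y"), source_dataset="D1", density=0.5),
    ]
    path = tmp_path / "c.tsv"
    write_clusters(clusters, path)
    back = read_clusters(path, source="D1")
    assert [c.probe_ids for c in back] == [c.probe_ids for c in clusters]
    assert back[0].density == pytest.approx(0.75)
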