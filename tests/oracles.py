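"""Independent brute-force reference implementations used only by the tests.

Each oracle re-derives a quantity from first principles in plain Python so
the package's vectorized implementations are checked against a second,
structurally different code path.
"""

from __future__ import annotations

import math


def percentile_linear(values, q):
    """q-th percentile with linear interpolation between order statistics."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    pos = (len(xs) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return xs[lo]
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def brute_filter_survivors(values_by_probe, var_pct, mean_pct):
    """Probe ids surviving the sequential variance-then-mean filters.

    ``values_by_probe``: dict probe -> list of floats (no missing values).
    Variance is the sample variance (denominator n-1); thresholds remove
    probes strictly below the percentile.
    """

    def var(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)

    probes = list(values_by_probe)
    variances = {p: var(values_by_probe[p]) for p in probes}
    v_thr = percentile_linear(list(variances.values()), var_pct)
    stage2 = [p for p in probes if variances[p] >= v_thr]
    means = {p: sum(values_by_probe[p]) / len(values_by_probe[p]) for p in stage2}
    m_thr = percentile_linear(list(means.values()), mean_pct)
    return [p for p in stage2 if means[p] >= m_thr]


def spearman(xs, ys):
    """Spearman correlation with average ranks, plain-Python."""

    def avg_ranks(vs):
        order = sorted(range(len(vs)), key=lambda i: vs[i])
        ranks = [0.0] * len(vs)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and vs[order[j + 1]] == vs[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(xs), avg_ranks(ys)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return 0.0
    return num / (dx * dy)


def subgraph_density(weights, members):
    """Mean pairwise weight over C(k, 2); ``weights`` maps frozenset pairs."""
    members = list(members)
    k = len(members)
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += weights.get(frozenset((members[i], members[j])), 0.0)
    return total / (k * (k - 1) / 2.0)


def simulate_miner(node_ids, weights, gamma, lam, t, beta, min_size):
    """Step-by-step re-enactment of the greedy quasi-clique rules.

    ``weights``: dict frozenset({a, b}) -> weight.  Returns the merged
    cluster list as lists of probe ids (mining order preserved before the
    final size-descending merge sort), mirroring seed eligibility, greedy
    growth with the decay-rate acceptance d_new >= alpha_n * max(gamma, d),
    the minimum-size drop and the fixed-point overlap merge.
    """
    edges = sorted(
        (
            (-w, *sorted(pair))
            for pair, w in weights.items()
            if w >= gamma
        )
    )
    grown: list[list[str]] = []
    for negw, a, b in edges:
        if any(a in c and b in c for c in grown):
            continue
        members = [a, b]
        while True:
            outside = [v for v in node_ids if v not in members]
            if not outside:
                break
            gains = {
                v: sum(
                    weights.get(frozenset((v, m)), 0.0) for m in members
                )
                for v in outside
            }
            best_gain = max(gains.values())
            best = min(v for v, g in gains.items() if g == best_gain)
            k = len(members)
            internal = subgraph_density(weights, members) * (k * (k - 1) / 2.0)
            new_density = (internal + gains[best]) / (k * (k + 1) / 2.0)
            alpha = 1.0 - 1.0 / (2.0 * lam * (k + t))
            current = internal / (k * (k - 1) / 2.0)
            if new_density < alpha * max(gamma, current):
                break
            members.append(best)
        grown.append(members)

    kept = [c for c in grown if len(c) >= min_size]

    def key(c):
        return (-len(c), tuple(sorted(c)))

    work = sorted(kept, key=key)
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                inter = len(set(work[i]) & set(work[j]))
                if inter / min(len(work[i]), len(work[j])) > beta:
                    union = sorted(set(work[i]) | set(work[j]))
                    work = [c for k2, c in enumerate(work) if k2 not in (i, j)]
                    work.append(union)
                    work.sort(key=key)
                    changed = True
                    break
            if changed:
                break
    return work


def first_pc_scores(matrix):
    """Per-sample scores of the first principal component of row-standardized
    data, via eigendecomposition of the probe covariance (plain numpy)."""
    import numpy as np

    X = np.asarray(matrix, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    Z = (X - mu) / sd
    C = Z @ Z.T / (Z.shape[1] - 1)
    evals, evecs = np.linalg.eigh(C)
    w = evecs[:, -1]
    return w @ Z
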