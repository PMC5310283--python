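"""Readers and probe filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panmethyl.exceptions import DataError
from panmethyl.io import (
    BetaMatrix,
    ProbeAnnotation,
    read_beta_matrix,
    write_beta_matrix,
)
from panmethyl.preprocess import (
    check_min_samples,
    filter_probes,
    map_probes_to_genes,
    restrict_to_common_probes,
)

from .oracles import brute_filter_survivors, percentile_linear


def _bm(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return BetaMatrix(probes, samples, values)


# ---------------------------------------------------------------------------
# reading


def test_read_beta_matrix_parses_shape_and_missing(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "probe_id\ts1\ts2\n"
        "pA\t0.1\t0.9\n"
        "pB\t\t0.5\n"
        "pC\t0.3\t0.4\n"
    )
    bm = read_beta_matrix(path)
    assert (bm.n_probes, bm.n_samples) == (3, 2)
    assert np.isnan(bm.values[1, 0])


def test_read_beta_matrix_rejects_out_of_range_naming_cell(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text("probe_id\ts1\ts2\npA\t0.1\t1.2\n")
    with pytest.raises(DataError, match="pA") as err:
        read_beta_matrix(path)
    assert "s2" in str(err.value)


@pytest.mark.parametrize(
    "text, match",
    [
        ("probe_id\ts1\npA\t0.2\npA\t0.3\n", "duplicate probe"),
        ("probe_id\ts1\ts1\npA\t0.2\t0.3\n", "duplicate sample"),
        ("probe_id\ts1\npA\tabc\n", "non-numeric"),
    ],
)
def test_read_beta_matrix_rejects_malformed(tmp_path, text, match):
    path = tmp_path / "m.tsv"
    path.write_text(text)
    with pytest.raises(DataError, match=match):
        read_beta_matrix(path)


def test_beta_matrix_write_read_roundtrip(tmp_path, tiny_bm):
    path = write_beta_matrix(tiny_bm, tmp_path / "m.tsv")
    back = read_beta_matrix(path)
    np.testing.assert_allclose(back.values, tiny_bm.values, atol=5e-7)


# ---------------------------------------------------------------------------
# filtering


def test_filter_matches_brute_force_on_distinct_variances():
    """10 probes with variances increasing 1..10: survivors must equal the
    independent percentile-and-threshold oracle's answer exactly."""
    rng = np.random.default_rng(0)
    base = rng.uniform(size=12)
    base = (base - base.mean()) / base.std()
    # distinct increasing variances AND distinct increasing means
    rows = [0.3 + 0.01 * k + 0.02 * np.sqrt(k) * base for k in range(1, 11)]
    bm = _bm(np.clip(rows, 0, 1))
    out, report = filter_probes(bm, var_percentile=30, mean_percentile=20)
    expected = brute_filter_survivors(
        {p: list(v) for p, v in zip(bm.probe_ids, bm.values)}, 30, 20
    )
    assert out.probe_ids == expected
    assert report.n_output == len(expected)
    # sanity on the oracle itself: the 30th percentile of 1..10 (scaled)
    # lies above the 3 smallest variances
    assert percentile_linear(list(range(1, 11)), 30) == pytest.approx(3.7)


def test_probe_with_missing_value_removed_first():
    vals = np.array(
        [[0.1, 0.9, 0.5, 0.2], [0.4, np.nan, 0.6, 0.5], [0.2, 0.8, 0.3, 0.7]]
    )
    out, report = filter_probes(_bm(vals), var_percentile=0, mean_percentile=0)
    assert report.n_removed_missing == 1
    assert "p1" not in out.probe_ids


def test_zero_percentiles_are_a_no_op(tiny_bm):
    out, report = filter_probes(tiny_bm, var_percentile=0, mean_percentile=0)
    assert out.probe_ids == tiny_bm.probe_ids
    np.testing.assert_array_equal(out.values, tiny_bm.values)
    assert report.n_output == report.n_input


def test_filter_removing_everything_raises():
    constant = _bm(np.full((3, 4), 0.5))
    with pytest.raises(DataError):
        # all variances equal -> none strictly below threshold; force removal
        # through the missing-value stage instead
        vals = np.full((3, 4), np.nan)
        filter_probes(_bm(vals))
    # constant matrix survives (nothing strictly below an all-equal threshold)
    out, _ = filter_probes(constant)
    assert out.n_probes == 3


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(0, 90), st.integers(0, 90))
def test_filter_output_is_subset_without_missing(seed, var_pct, mean_pct):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0, 1, size=(25, 8))
    vals[rng.random(size=vals.shape) < 0.02] = np.nan
    bm = _bm(vals)
    try:
        out, _ = filter_probes(bm, var_pct, mean_pct)
    except DataError:
        return
    assert set(out.probe_ids) <= set(bm.probe_ids)
    assert not np.isnan(out.values).any()


# ---------------------------------------------------------------------------
# platform matching, sample rule, gene mapping


def test_restrict_to_common_probes_keeps_intersection_in_order(tiny_bm):
    out = restrict_to_common_probes(tiny_bm, ["p3", "p1", "zzz"])
    assert out.probe_ids == ["p1", "p3"]  # bm order, not reference order
    again = restrict_to_common_probes(out, ["p3", "p1", "zzz"])
    assert again.probe_ids == out.probe_ids


def test_restrict_to_common_probes_superset_is_identity(tiny_bm):
    out = restrict_to_common_probes(tiny_bm, tiny_bm.probe_ids + ["extra"])
    assert out.probe_ids == tiny_bm.probe_ids


def test_restrict_to_common_probes_disjoint_raises(tiny_bm):
    with pytest.raises(DataError):
        restrict_to_common_probes(tiny_bm, ["nope"])


@pytest.mark.parametrize("n, expected", [(50, True), (49, False), (0, False)])
def test_min_sample_rule_boundary(n, expected):
    if n == 0:
        bm = None
        assert check_min_samples(_bm(np.empty((2, 0))), 50) is False
        return
    bm = _bm(np.full((2, n), 0.5))
    assert check_min_samples(bm, 50) is expected


def test_gene_mapping_first_member_and_dedup():
    ann = ProbeAnnotation(
        ["pa", "pb", "pc"],
        [("GSTT1", "GSTT2"), ("GSTT1",), ("NEXT",)],
        ["chr22", "chr22", "chr1"],
    )
    # family probe contributes only its first member; duplicates collapse
    assert map_probes_to_genes(["pa", "pb", "pc"], ann) == ["GSTT1", "NEXT"]
    assert map_probes_to_genes([], ann) == []
    # unannotated probes are dropped
    assert map_probes_to_genes(["pa", "unknown"], ann) == ["GSTT1"]
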