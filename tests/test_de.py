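"""NB Wald pipeline: normalization, dispersion, the test itself, FDR, classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

import mscikit as mk
from mscikit.de import (
    DEError,
    bh_adjust,
    classify_genes,
    compute_size_factors,
    compute_tpm,
    estimate_dispersions,
    stage_contrast,
    wald_stage_contrast,
)


def df(data, cols=None):
    out = pd.DataFrame(data, columns=cols)
    out.index = [f"g{i}" for i in range(len(out))]
    return out


# --- size factors ------------------------------------------------------------


def test_size_factors_hand_case():
    counts = df([[4, 16], [1, 4]], cols=["s1", "s2"])
    sf = compute_size_factors(counts)
    assert sf.to_list() == pytest.approx([0.5, 2.0])


def test_size_factors_identical_samples_are_one():
    counts = df([[7, 7, 7], [3, 3, 3], [100, 100, 100]], cols=list("abc"))
    assert compute_size_factors(counts).to_list() == pytest.approx([1.0, 1.0, 1.0])


def test_size_factor_ratios_are_scale_equivariant():
    # scaling one column by 3 also moves the data-derived geometric-mean
    # reference, so individual factors shift; the *ratios* between factors
    # transform exactly (factor_c : factor_j gains the factor of 3)
    rng = np.random.default_rng(0)
    counts = df(rng.poisson(50, size=(200, 4)), cols=list("abcd"))
    base = compute_size_factors(counts)
    scaled = counts.copy()
    scaled["c"] = scaled["c"] * 3
    out = compute_size_factors(scaled)
    for s in "abd":
        assert out["c"] / out[s] == pytest.approx(3 * base["c"] / base[s])
    assert out["a"] / out["b"] == pytest.approx(base["a"] / base["b"])


def test_size_factors_error_without_common_nonzero_gene():
    counts = df([[0, 5], [5, 0]], cols=["s1", "s2"])
    with pytest.raises(DEError, match="pseudo-reference"):
        compute_size_factors(counts)


# --- TPM ---------------------------------------------------------------------


def test_tpm_closed_form_and_column_sums():
    counts = df([[10, 30], [10, 30]], cols=["s1", "s2"])
    lengths = pd.Series([1000, 2000], index=counts.index)
    tpm = compute_tpm(counts, lengths)
    assert tpm.iloc[0].to_list() == pytest.approx([2e6 / 3, 2e6 / 3])
    assert tpm.iloc[1].to_list() == pytest.approx([1e6 / 3, 1e6 / 3])
    assert tpm.sum(axis=0).to_list() == pytest.approx([1e6, 1e6])


def test_tpm_equal_lengths_gives_equal_tpm_for_equal_counts():
    counts = df([[5, 8], [5, 8]], cols=["s1", "s2"])
    tpm = compute_tpm(counts, pd.Series([700, 700], index=counts.index))
    assert tpm.iloc[0].to_list() == pytest.approx(tpm.iloc[1].to_list())


# --- dispersion --------------------------------------------------------------


def test_dispersion_direct_formula():
    counts = df([[10, 20, 30]], cols=["a", "b", "c"])
    sf = pd.Series(1.0, index=counts.columns)
    alpha = estimate_dispersions(counts, sf, [["a", "b", "c"]])
    assert alpha.iloc[0] == pytest.approx((100 - 20) / 400)


def test_dispersion_poisson_data_near_floor():
    rng = np.random.default_rng(1)
    counts = df(rng.poisson(200, size=(4000, 6)), cols=list("abcdef"))
    sf = pd.Series(1.0, index=counts.columns)
    alpha = estimate_dispersions(counts, sf, [list("abc"), list("def")])
    assert np.median(alpha) < 0.01  # no overdispersion to find


def test_dispersion_recovers_simulated_alpha():
    cfg = mk.null_config(
        3, n_genes_per_class={"Autosome": 5000}, dispersion=0.2,
        baseline_log2_mean_dist=(7.0, 1.0), n_replicates=6,
    )
    dataset, _, _ = mk.simulate_experiment(cfg)
    sf = compute_size_factors(dataset.counts)
    groups = [dataset.stage_samples(s) for s in dataset.stages_present()]
    alpha = estimate_dispersions(dataset.counts, sf, groups)
    assert np.median(alpha.dropna()) == pytest.approx(0.2, rel=0.2)


# --- Wald contrast -----------------------------------------------------------


def _wald(counts, alpha, na, nb):
    cols = counts.columns
    sf = pd.Series(1.0, index=cols)
    disp = pd.Series(alpha, index=counts.index, dtype=float)
    return wald_stage_contrast(counts, sf, disp, list(cols[:na]), list(cols[na:]))


def test_exact_fourfold_ratio_gives_log2fc_two():
    counts = df([[10, 20, 30, 40, 80, 120]], cols=list("abcdef"))
    res = _wald(counts, 0.05, 3, 3)
    assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)


def test_identical_groups_give_null_result():
    counts = df([[12, 15, 9, 12, 15, 9]], cols=list("abcdef"))
    res = _wald(counts, 0.1, 3, 3)
    assert res["log2fc"].iloc[0] == pytest.approx(0.0, abs=1e-8)
    assert res["wald_p"].iloc[0] == pytest.approx(1.0, abs=1e-8)


def test_wald_matches_likelihood_oracle():
    """Toy gene vs an independent profile-likelihood + Fisher-information oracle."""
    a_counts, b_counts, alpha = np.array([5.0, 7.0, 6.0]), np.array([14.0, 13.0, 15.0]), 0.05

    def nb_negll(mu, y):
        r = 1.0 / alpha
        return -np.sum(stats.nbinom.logpmf(y, r, r / (r + mu)))

    mu_a = minimize_scalar(nb_negll, bounds=(1e-3, 50), args=(a_counts,), method="bounded").x
    mu_b = minimize_scalar(nb_negll, bounds=(1e-3, 50), args=(b_counts,), method="bounded").x
    lfc_oracle = np.log2(mu_b / mu_a)
    var_oracle = (1 + alpha * mu_a) / (3 * mu_a) + (1 + alpha * mu_b) / (3 * mu_b)
    z = (lfc_oracle * np.log(2)) / np.sqrt(var_oracle)
    p_oracle = 2 * stats.norm.sf(abs(z))

    counts = df([np.concatenate([a_counts, b_counts])], cols=list("abcdef"))
    res = _wald(counts, alpha, 3, 3)
    assert res["log2fc"].iloc[0] == pytest.approx(lfc_oracle, abs=1e-3)
    assert res["wald_p"].iloc[0] == pytest.approx(p_oracle, abs=1e-3)


def test_label_swap_negates_log2fc_and_keeps_p():
    rng = np.random.default_rng(2)
    counts = df(rng.poisson(40, size=(50, 6)), cols=list("abcdef"))
    fwd = _wald(counts, 0.1, 3, 3)
    cols = list(counts.columns)
    sf = pd.Series(1.0, index=cols)
    disp = pd.Series(0.1, index=counts.index)
    rev = wald_stage_contrast(counts, sf, disp, cols[3:], cols[:3])
    ok = fwd["converged"] & rev["converged"]
    assert np.allclose(fwd.loc[ok, "log2fc"], -rev.loc[ok, "log2fc"], atol=1e-6)
    assert np.allclose(fwd.loc[ok, "wald_p"], rev.loc[ok, "wald_p"], atol=1e-6)


def test_global_size_factor_rescaling_is_exactly_invariant():
    # multiplying every size factor by a constant only shifts the intercept;
    # the contrast coefficient, its SE and the p-value are untouched
    rng = np.random.default_rng(3)
    counts = df(rng.poisson(60, size=(40, 6)), cols=list("abcdef"))
    cols = list(counts.columns)
    disp = pd.Series(0.1, index=counts.index)
    sf = pd.Series([0.8, 1.0, 1.3, 0.9, 1.1, 1.0], index=cols)
    base = wald_stage_contrast(counts, sf, disp, cols[:3], cols[3:])
    out = wald_stage_contrast(counts, 7.0 * sf, disp, cols[:3], cols[3:])
    assert np.allclose(base["log2fc"], out["log2fc"], atol=1e-6)
    assert np.allclose(base["wald_p"], out["wald_p"], atol=1e-6, equal_nan=True)


def test_joint_column_and_factor_rescaling_is_nearly_invariant():
    # rescaling one sample's counts together with its size factor is not an
    # exact NB-likelihood invariance (the mean-variance link sees the raw
    # scale), but estimates should move only slightly
    rng = np.random.default_rng(3)
    counts = df(rng.poisson(60, size=(40, 6)), cols=list("abcdef"))
    cols = list(counts.columns)
    disp = pd.Series(0.1, index=counts.index)
    sf = pd.Series(1.0, index=cols)
    base = wald_stage_contrast(counts, sf, disp, cols[:3], cols[3:])
    scaled = counts.copy()
    scaled["e"] = scaled["e"] * 5
    sf2 = sf.copy()
    sf2["e"] = 5.0
    out = wald_stage_contrast(scaled, sf2, disp, cols[:3], cols[3:])
    assert np.allclose(base["log2fc"], out["log2fc"], atol=0.05)


def test_low_expression_genes_are_untested():
    counts = df([[0, 1, 0, 0, 0, 1], [50, 60, 55, 40, 45, 50]], cols=list("abcdef"))
    res = _wald(counts, 0.1, 3, 3)
    assert not res["tested"].iloc[0]
    assert res["tested"].iloc[1]


# --- BH + classification -----------------------------------------------------


def test_bh_hand_case():
    q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_and_nan_passthrough():
    assert bh_adjust(np.array([0.3])) == pytest.approx([0.3])
    q = bh_adjust(pd.Series([0.01, np.nan, 0.5]))
    assert np.isnan(q.iloc[1]) and q.iloc[0] == pytest.approx(0.02)


def test_bh_monotone_in_p_order():
    rng = np.random.default_rng(4)
    p = rng.random(200)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert ((q >= 0) & (q <= 1)).all()


def test_bh_rejects_invalid_p():
    with pytest.raises(DEError):
        bh_adjust(np.array([0.5, 1.2]))


@pytest.mark.parametrize(
    "q,lfc,tested,expected",
    [
        (0.01, -1.0, True, "down"),
        (0.01, 1.0, True, "up"),
        (0.20, -3.0, True, "unchanged"),
        (0.01, -1.0, False, "untested"),
    ],
)
def test_classification_rules(q, lfc, tested, expected):
    table = pd.DataFrame(
        {"log2fc": [lfc], "wald_p": [q], "tested": [tested]}, index=["g"]
    )
    out = classify_genes(table, q_threshold=0.05)
    assert out["class"].iloc[0] == expected


def test_power_on_strong_msci_simulation():
    """>= 90% of genes silenced at -2 log2 are recovered as 'down'."""
    cfg = mk.msci_config(
        seed=42, msci_fraction=0.3, msci_log2fc=-2.0, dispersion=0.05,
        purity=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        baseline_log2_mean_dist=(7.0, 1.5),  # well-expressed genes
        n_genes_per_class={"X": 1000, "Autosome": 3000},
    )
    dataset, _, truth = mk.simulate_experiment(cfg)
    de = stage_contrast(dataset, "meiosis", "mitosis")
    affected = truth.genes.index[truth.genes["msci_affected"]]
    recovered = (de.loc[affected, "class"] == "down").mean()
    assert recovered >= 0.90
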