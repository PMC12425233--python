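"""Negative-binomial differential expression between spermatogenesis stages.

Implements a deliberately transparent NB Wald pipeline: median-of-ratios
size factors, method-of-moments gene-wise dispersions (no shrinkage), a
per-gene two-group NB GLM with log link and log-size-factor offsets fitted
by iteratively reweighted least squares at fixed dispersion, a two-sided
normal Wald p-value on the group coefficient, and Benjamini-Hochberg FDR.
Genes are then classified as down/up-regulated in the numerator stage
relative to the denominator stage (e.g. meiosis vs mitosis, the MSCI
contrast), unchanged, or untested (below the expression filter).

The NB variance convention is Var = mu + alpha * mu**2; alpha = 0 is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)

DEFAULT_Q_THRESHOLD = 0.05
DEFAULT_MIN_MEAN = 1.0  # independent expression filter on mean normalized count
DEFAULT_ALPHA_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


class DEError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normalization


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample j, the factor is the median over genes of
    ``count_gj / geometric_mean_g`` where the geometric mean runs over
    samples and only genes with strictly positive counts in *all* samples
    participate.
    """
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        raise DEError(
            "no gene has nonzero counts in every sample; supply a pseudo-reference "
            "or filter samples before normalization"
        )
    sub = mat[usable]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and gene lengths (bp).

    ``tpm_gj = (c_gj / L_g) / sum_h (c_hj / L_h) * 1e6``; columns sum to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise DEError("every gene needs a length for TPM computation")
    lvals = lengths.to_numpy(dtype=float)
    if (lvals <= 0).any():
        raise DEError("gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lvals[:, None]
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        raise DEError("a sample has zero total counts; TPM undefined")
    return pd.DataFrame(rate / denom * 1e6, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: list[list[str]],
    alpha_floor: float = DEFAULT_ALPHA_FLOOR,
) -> pd.Series:
    """Method-of-moments gene-wise NB dispersions.

    Within each replicate group the moment estimator is
    ``(s^2 - m) / m^2`` on normalized counts; estimates are combined across
    groups weighted by degrees of freedom (n_k - 1) and floored at
    ``alpha_floor``.  Genes with zero mean in every group get NaN (untested).
    """
    norm_counts = counts.to_numpy(dtype=float) / size_factors.reindex(
        counts.columns
    ).to_numpy()
    col_idx = {c: i for i, c in enumerate(counts.columns)}
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    any_mean = np.zeros(len(counts), dtype=bool)
    for group in groups:
        cols = [col_idx[s] for s in group]
        if len(cols) < 2:
            continue
        sub = norm_counts[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        ok = m > 0
        num[ok] += df * a[ok]
        den[ok] += df
        any_mean |= ok
    if (den == 0).all():
        raise DEError("dispersion estimation needs >= 2 replicates in >= 1 group")
    with np.errstate(invalid="ignore"):
        alpha = np.where(den > 0, np.maximum(alpha_floor, num / np.maximum(den, 1)), np.nan)
    alpha[~any_mean] = np.nan
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Wald contrast


@dataclass
class WaldResult:
    table: pd.DataFrame  # log2fc, se, wald_p, converged, mean_norm, tested


def wald_stage_contrast(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    group_a: list[str],
    group_b: list[str],
    min_mean: float = DEFAULT_MIN_MEAN,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B (numerator) vs group A (denominator).

    Fits ``log mu_ij = beta0 + beta1 * 1[j in B] + log sf_j`` by IRLS at the
    gene's fixed dispersion; ``log2fc = beta1 / ln 2``, the standard error
    comes from the Fisher information at the fit, and ``wald_p`` is the
    two-sided normal tail of beta1 / SE.  Genes whose mean normalized count
    falls below ``min_mean`` (or with undefined dispersion) are untested.
    """
    if not group_a or not group_b:
        raise DEError("both contrast groups must be non-empty")
    cols = list(group_a) + list(group_b)
    y = counts[cols].to_numpy(dtype=float)
    sf = size_factors.reindex(cols).to_numpy(dtype=float)
    x = np.array([0.0] * len(group_a) + [1.0] * len(group_b))
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)

    mean_norm = (y / sf).mean(axis=1)
    tested = (mean_norm >= min_mean) & np.isfinite(alpha)

    n_genes = len(counts)
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    converged = np.zeros(n_genes, dtype=bool)

    if tested.any():
        b0, b1, se1, conv = _irls_two_group(
            y[tested], sf, x, alpha[tested], tol=tol, max_iter=max_iter
        )
        z = np.where(se1 > 0, b1 / se1, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        log2fc[tested] = b1 / LN2
        se[tested] = se1 / LN2
        pval[tested] = np.where(conv, p, np.nan)
        converged[tested] = conv

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "wald_p": pval,
            "converged": converged,
            "mean_norm": mean_norm,
            "tested": tested,
        },
        index=counts.index,
    )


def _irls_two_group(
    y: np.ndarray,
    sf: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Vectorized IRLS for the 2-parameter NB GLM, one fit per row of ``y``.

    Working weights are the expected-information weights mu / (1 + alpha*mu).
    Linear predictors are clamped to keep exp() finite for degenerate genes
    (e.g. an all-zero group), which are reported as non-converged when the
    coefficient update never settles.
    """
    g = y.shape[0]
    off = np.log(sf)[None, :]
    in_b = x[None, :]
    eps = 1e-8
    mean_a = (y[:, x == 0] / sf[x == 0]).mean(axis=1)
    mean_b = (y[:, x == 1] / sf[x == 1]).mean(axis=1)
    b0 = np.log(np.maximum(mean_a, eps))
    b1 = np.log(np.maximum(mean_b, eps)) - b0
    a = alpha[:, None]

    active = np.ones(g, dtype=bool)
    converged = np.zeros(g, dtype=bool)
    s00 = s01 = s11 = det = None
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * in_b, -30.0, 30.0)
        mu = np.exp(eta + off)
        w = mu / (1.0 + a * mu)
        z = eta + (y - mu) / mu
        s00 = w.sum(axis=1)
        s01 = (w * in_b).sum(axis=1)
        s11 = (w * in_b**2).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * in_b * z).sum(axis=1)
        det = s00 * s11 - s01**2
        bad = det <= 0
        det_safe = np.where(bad, 1.0, det)
        b0_new = np.where(bad, b0, (s11 * t0 - s01 * t1) / det_safe)
        b1_new = np.where(bad, b1, (s00 * t1 - s01 * t0) / det_safe)
        b1_new = np.clip(b1_new, -30.0, 30.0)
        b0_new = np.clip(b0_new, -30.0, 30.0)
        delta = np.maximum(np.abs(b0_new - b0), np.abs(b1_new - b1))
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
        b0, b1 = b0_new, b1_new
        if not active.any():
            break
    var_b1 = np.where(det > 0, s00 / np.where(det > 0, det, 1.0), np.inf)
    se1 = np.sqrt(var_b1)
    return b0, b1, se1, converged


# ---------------------------------------------------------------------------
# FDR + classification


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    arr = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise DEError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    if ok.any():
        q[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def classify_genes(
    wald_table: pd.DataFrame, q_threshold: float = DEFAULT_Q_THRESHOLD
) -> pd.DataFrame:
    """Attach BH q-values and the down/up/unchanged/untested class."""
    out = wald_table.copy()
    out["q"] = bh_adjust(out["wald_p"])
    cls = np.full(len(out), "unchanged", dtype=object)
    sig = out["q"].to_numpy() < q_threshold
    lfc = out["log2fc"].to_numpy()
    cls[np.where(sig & (lfc < 0))[0]] = "down"
    cls[np.where(sig & (lfc > 0))[0]] = "up"
    cls[~out["tested"].to_numpy()] = "untested"
    out["class"] = cls
    return out


def stage_contrast(
    dataset,
    numerator: str,
    denominator: str,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_mean: float = DEFAULT_MIN_MEAN,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """End-to-end stage contrast on an :class:`ExpressionDataset`.

    Normalizes, estimates dispersions from all stage groups, runs the Wald
    test of ``numerator`` vs ``denominator`` and classifies genes.  ``down``
    means downregulated in the numerator stage (for meiosis vs mitosis, the
    MSCI-consistent direction on the X).
    """
    group_a = dataset.stage_samples(denominator)
    group_b = dataset.stage_samples(numerator)
    if size_factors is None:
        size_factors = compute_size_factors(dataset.counts)
    if dispersions is None:
        groups = [dataset.stage_samples(s) for s in dataset.stages_present()]
        dispersions = estimate_dispersions(dataset.counts, size_factors, groups)
    table = wald_stage_contrast(
        dataset.counts, size_factors, dispersions, group_a, group_b, min_mean=min_mean
    )
    result = classify_genes(table, q_threshold=q_threshold)
    result.insert(0, "contrast", f"{numerator}:{denominator}")
    return result
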