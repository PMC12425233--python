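"""X-to-autosome (X:AA) expression ratio estimators.

The naive ratio of overall median expression inflates X:AA estimates
because the X and the autosomes differ in the share of genes expressed at
all.  The matched-fraction ("filter-by-fraction") estimator fixes this: at
each TPM threshold t, compute each class's fraction of genes with
expression strictly above t, take the smallest fraction f across
participating classes, and compare the medians of each class's top-f
expressed genes.  A simple-threshold ("by expression") estimator — the
median of values above t per class — is kept for comparison.  With a neo-X
present, f is the three-way minimum across X, neo-X and autosomes and both
X:AA and NeoX:AA share it.

Thresholds follow the strict convention > 0, > 2 and > 10 TPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import STAGES, ExpressionDataset

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.0, 2.0, 10.0)


class XAAError(ValueError):
    pass


def fraction_above(expr: np.ndarray | pd.Series, t: float) -> float:
    """Fraction of genes with expression strictly above threshold ``t``."""
    arr = np.asarray(expr, dtype=float)
    if arr.size == 0:
        raise XAAError("cannot compute a fraction on an empty expression vector")
    return float((arr > t).sum()) / arr.size


def select_top_fraction(expr: pd.Series, f: float) -> pd.Series:
    """Top fraction ``f`` of genes by expression (k = floor(f*n + 1e-9), >= 1).

    Boundary ties are broken by stable gene-id order so the selection is
    deterministic; the class attaining the minimum fraction recovers exactly
    its above-threshold set.
    """
    if not 0 < f <= 1:
        raise XAAError("fraction must lie in (0, 1]")
    n = len(expr)
    if n == 0:
        raise XAAError("empty expression vector")
    k = max(1, int(np.floor(f * n + 1e-9)))
    by_id = expr.sort_index()
    # lexsort: descending expression, ties in ascending gene-id order
    order = np.lexsort((np.arange(n), -by_id.to_numpy(dtype=float)))
    return by_id.iloc[order[:k]]


@dataclass
class XAAResult:
    """One matched-fraction or simple-threshold ratio estimate."""

    stage: str
    method: str  # by_fraction / by_expression
    threshold: float
    numerator_class: str  # X or NeoX
    ratio: float
    f_used: float
    n_top_num: int
    n_top_den: int
    replicate: str  # replicate label or "pooled"
    defined: bool = True


def xaa_filter_by_fraction(
    x_expr: pd.Series,
    a_expr: pd.Series,
    t: float,
    neox_expr: pd.Series | None = None,
    stage: str = "",
    replicate: str = "pooled",
) -> list[XAAResult]:
    """Matched-fraction X:AA (and NeoX:AA) at one threshold.

    ``f`` is the minimum above-threshold fraction over the participating
    classes; the ratio divides the median of the numerator class's top-f
    genes by the median of the autosomes' top-f genes.  A participating
    class with no gene above ``t`` makes the estimate undefined.
    """
    if len(x_expr) == 0 or len(a_expr) == 0:
        raise XAAError("X and autosome classes must both be non-empty")
    participating = {"X": x_expr, "Autosome": a_expr}
    if neox_expr is not None:
        if len(neox_expr) == 0:
            raise XAAError("neo-X class supplied but empty")
        participating["NeoX"] = neox_expr
    fractions = {cls: fraction_above(v, t) for cls, v in participating.items()}
    numerators = ["X"] + (["NeoX"] if neox_expr is not None else [])
    if min(fractions.values()) == 0.0:
        return [
            XAAResult(stage, "by_fraction", t, num, np.nan, 0.0, 0, 0, replicate, False)
            for num in numerators
        ]
    f = min(fractions.values())
    tops = {cls: select_top_fraction(v, f) for cls, v in participating.items()}
    med_a = float(np.median(tops["Autosome"]))
    out = []
    for num in numerators:
        ratio = float(np.median(tops[num])) / med_a
        out.append(
            XAAResult(
                stage, "by_fraction", t, num, ratio, f,
                len(tops[num]), len(tops["Autosome"]), replicate,
            )
        )
    return out


def xaa_by_expression(
    x_expr: pd.Series,
    a_expr: pd.Series,
    t: float,
    neox_expr: pd.Series | None = None,
    stage: str = "",
    replicate: str = "pooled",
) -> list[XAAResult]:
    """Simple-threshold ratio: median(values > t) per class, no matching."""
    if len(x_expr) == 0 or len(a_expr) == 0:
        raise XAAError("X and autosome classes must both be non-empty")
    participating = {"X": x_expr, "Autosome": a_expr}
    if neox_expr is not None:
        participating["NeoX"] = neox_expr
    above = {cls: np.asarray(v, dtype=float) for cls, v in participating.items()}
    above = {cls: v[v > t] for cls, v in above.items()}
    numerators = ["X"] + (["NeoX"] if neox_expr is not None else [])
    out = []
    for num in numerators:
        if above[num].size == 0 or above["Autosome"].size == 0:
            out.append(
                XAAResult(stage, "by_expression", t, num, np.nan, np.nan, 0, 0, replicate, False)
            )
            continue
        ratio = float(np.median(above[num])) / float(np.median(above["Autosome"]))
        out.append(
            XAAResult(
                stage, "by_expression", t, num, ratio, np.nan,
                int(above[num].size), int(above["Autosome"].size), replicate,
            )
        )
    return out


def xaa_table(
    dataset: ExpressionDataset,
    annotation: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    methods: tuple[str, ...] = ("by_fraction", "by_expression"),
    biotype: str = "coding",
) -> pd.DataFrame:
    """All (stage, threshold, method) ratios, per replicate and pooled.

    Per-replicate expression is the sample's TPM; pooled expression is the
    mean TPM across a stage's replicates.  NeoX:AA rows appear whenever the
    annotation contains NeoX genes.
    """
    ann = annotation[annotation["biotype"] == biotype]
    ids = {
        cls: ann.index[ann["chromosome_class"] == cls].intersection(dataset.gene_ids)
        for cls in ("X", "NeoX", "Autosome")
    }
    if len(ids["X"]) == 0 or len(ids["Autosome"]) == 0:
        raise XAAError("need annotated X and autosomal genes in the dataset")
    has_neox = len(ids["NeoX"]) > 0
    fn = {"by_fraction": xaa_filter_by_fraction, "by_expression": xaa_by_expression}

    rows: list[XAAResult] = []
    for stage in dataset.stages_present():
        samples = dataset.stage_samples(stage)
        scopes = [(s, dataset.tpm[s]) for s in samples]
        scopes.append(("pooled", dataset.tpm[samples].mean(axis=1)))
        for rep_label, expr in scopes:
            x = expr.loc[ids["X"]]
            a = expr.loc[ids["Autosome"]]
            nx = expr.loc[ids["NeoX"]] if has_neox else None
            for method in methods:
                for t in thresholds:
                    rows.extend(
                        fn[method](x, a, t, neox_expr=nx, stage=stage, replicate=rep_label)
                    )
    return pd.DataFrame([r.__dict__ for r in rows])


def stage_ratio_comparison(xaa_results: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of per-replicate ratios across stages.

    Run separately per (method, threshold, numerator class); exact
    distribution for small untied samples, normal approximation with tie and
    continuity corrections otherwise.  Star annotations use the 0.05 / 0.01
    thresholds.
    """
    per_rep = xaa_results[(xaa_results["replicate"] != "pooled") & xaa_results["defined"]]
    rows = []
    grp_cols = ["method", "threshold", "numerator_class"]
    for key, sub in per_rep.groupby(grp_cols):
        stages = [s for s in STAGES if s in set(sub["stage"])]
        for i, s1 in enumerate(stages):
            for s2 in stages[i + 1 :]:
                v1 = sub.loc[sub["stage"] == s1, "ratio"].to_numpy()
                v2 = sub.loc[sub["stage"] == s2, "ratio"].to_numpy()
                if len(v1) < 2 or len(v2) < 2:
                    continue
                p = wilcoxon_rank_sum(v1, v2)
                rows.append(
                    dict(
                        zip(grp_cols, key),
                        stage_a=s1,
                        stage_b=s2,
                        n_a=len(v1),
                        n_b=len(v2),
                        p=p,
                        stars="**" if p <= 0.01 else ("*" if p <= 0.05 else ""),
                    )
                )
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both samples are small (min n <= 10) and
    untied; otherwise the normal approximation with continuity and tie
    correction.  Completely tied data gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise XAAError("rank-sum test needs two non-empty groups")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
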