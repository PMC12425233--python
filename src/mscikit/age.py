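"""Gene-age-stratified expression trajectories across spermatogenesis.

Newly evolved genes (age branches 1-6) and old genes (branch 0) follow
different stage trajectories: new X-linked genes are elevated during
mitosis and meiosis (escaping MSCI), while new autosomal genes climb toward
their post-meiotic peak, converging with the new X genes after meiosis —
the signature of haploid selection.  This module computes mean log2
normalized expression (+/- SEM) per (age group x chromosome class x stage)
cell and tests the relevant group contrasts with Wilcoxon rank-sum, genes
being the sampling unit (per-gene values average replicates first).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .annotation import assign_age_group
from .dataset import STAGES, ExpressionDataset
from .de import compute_size_factors
from .xaa import wilcoxon_rank_sum

DEFAULT_PSEUDOCOUNT = 1.0


class AgeError(ValueError):
    pass


def per_gene_stage_values(
    dataset: ExpressionDataset,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "size_factor",
) -> pd.DataFrame:
    """Per-gene log2 expression per stage (replicates averaged after log).

    ``normalization`` is ``"size_factor"`` (median-of-ratios normalized
    counts, the default) or ``"tpm"``.
    """
    if pseudocount <= 0:
        raise AgeError("pseudocount must be positive")
    if normalization == "size_factor":
        sf = compute_size_factors(dataset.counts)
        expr = dataset.counts / sf
    elif normalization == "tpm":
        expr = dataset.tpm
    else:
        raise AgeError(f"unknown normalization {normalization!r}")
    logged = np.log2(expr + pseudocount)
    out = {}
    for stage in dataset.stages_present():
        out[stage] = logged[dataset.stage_samples(stage)].mean(axis=1)
    return pd.DataFrame(out)


def stage_trajectories(
    dataset: ExpressionDataset,
    annotation: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "size_factor",
) -> pd.DataFrame:
    """Mean +/- SEM trajectory per (age group, chromosome class, stage).

    Cells with no genes (e.g. new genes on the dot chromosome) are simply
    absent from the output.  SEM uses the sample standard deviation over
    genes; a single-gene cell reports SEM 0.
    """
    values = per_gene_stage_values(dataset, pseudocount, normalization)
    ann = annotation.reindex(values.index)
    age_group = ann["age_branch"].map(assign_age_group)
    rows = []
    for (age, chrom_class), idx in values.groupby(
        [age_group, ann["chromosome_class"]]
    ).groups.items():
        if age == "unknown":
            continue
        sub = values.loc[idx]
        for stage in values.columns:
            v = sub[stage].dropna().to_numpy()
            if v.size == 0:
                continue
            sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
            rows.append(
                {
                    "age_group": age,
                    "chromosome_class": chrom_class,
                    "stage": stage,
                    "mean_log2": float(v.mean()),
                    "sem": sem,
                    "n_genes": int(v.size),
                }
            )
    return pd.DataFrame(rows)


#: contrasts of interest: is the new-X elevation real, does it differ from
#: new autosomal genes, and do old X genes drop from mitosis to meiosis?
def compare_age_location_groups(
    dataset: ExpressionDataset,
    annotation: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    normalization: str = "size_factor",
    min_genes: int = 2,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrasts across age x location groups.

    Per stage: new-X vs old-X and new-X vs new-autosome; plus old-X mitosis
    vs meiosis.  Groups smaller than ``min_genes`` are skipped with a
    warning.  Direction is the sign of the median difference (group A minus
    group B).
    """
    values = per_gene_stage_values(dataset, pseudocount, normalization)
    ann = annotation.reindex(values.index)
    age_group = ann["age_branch"].map(assign_age_group)

    def gene_set(age: str, chrom_class: str) -> pd.Index:
        return values.index[(age_group == age) & (ann["chromosome_class"] == chrom_class)]

    specs = []
    for stage in values.columns:
        specs.append(("new_X_vs_old_X", ("new", "X", stage), ("old", "X", stage)))
        specs.append(("new_X_vs_new_A", ("new", "X", stage), ("new", "Autosome", stage)))
    if {"mitosis", "meiosis"} <= set(values.columns):
        specs.append(("old_X_mitosis_vs_meiosis", ("old", "X", "mitosis"), ("old", "X", "meiosis")))

    rows = []
    for name, (age_a, cls_a, st_a), (age_b, cls_b, st_b) in specs:
        va = values.loc[gene_set(age_a, cls_a), st_a].dropna().to_numpy()
        vb = values.loc[gene_set(age_b, cls_b), st_b].dropna().to_numpy()
        if va.size < min_genes or vb.size < min_genes:
            warnings.warn(f"contrast {name} at {st_a}: group below {min_genes} genes; skipped")
            continue
        p = wilcoxon_rank_sum(va, vb)
        diff = float(np.median(va) - np.median(vb))
        rows.append(
            {
                "contrast": name,
                "stage": st_a if name != "old_X_mitosis_vs_meiosis" else "mitosis_vs_meiosis",
                "n_a": int(va.size),
                "n_b": int(vb.size),
                "median_diff": diff,
                "direction": "A>B" if diff > 0 else ("A<B" if diff < 0 else "tie"),
                "p": p,
            }
        )
    return pd.DataFrame(rows)
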