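"""Chromosomal enrichment of meiotically regulated genes.

An MSCI-consistent signature is a significantly higher proportion of
meiotically downregulated genes on the X (and neo-X) than on autosomes.
Proportions use all annotated genes of the biotype on each chromosome class
as denominators — not just tested genes — because not every annotated gene
is expressed during spermatogenesis and the class-level proportion is the
quantity of interest.  Each non-autosomal class is compared against the
autosomes with a Yates continuity-corrected chi-square on the 2x2 table of
regulated vs not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
LOW_POWER_MIN_TOTAL = 100  # dot-chromosome-sized classes carry little power


class EnrichmentError(ValueError):
    pass


def stars(p: float) -> str:
    """Significance stars at the conventional 0.05 / 0.01 / 0.001 levels."""
    if not np.isfinite(p):
        return ""
    for thr, mark in STAR_THRESHOLDS:
        if p <= thr:
            return mark
    return ""


def tabulate_class_counts(
    classes: pd.Series,
    annotation: pd.DataFrame,
    biotype: str = "coding",
) -> pd.DataFrame:
    """Down/up/total tallies per chromosome class.

    ``classes`` maps gene id to a DE class in {down, up, unchanged,
    untested}; every classified gene must appear in ``annotation``.  Totals
    are all annotated genes of ``biotype`` on the class, so proportions are
    relative to the annotated gene complement.
    """
    missing = classes.index.difference(annotation.index)
    if len(missing):
        raise EnrichmentError(f"classified genes missing from annotation: {list(missing)[:5]}")
    ann = annotation[annotation["biotype"] == biotype]
    cls = classes.reindex(ann.index)
    rows = []
    for chrom_class, sub in ann.groupby("chromosome_class"):
        sub_cls = cls.loc[sub.index]
        rows.append(
            {
                "chromosome_class": chrom_class,
                "n_down": int((sub_cls == "down").sum()),
                "n_up": int((sub_cls == "up").sum()),
                "n_tested": int(sub_cls.isin(["down", "up", "unchanged"]).sum()),
                "n_total": int(len(sub)),
            }
        )
    table = pd.DataFrame(rows).set_index("chromosome_class")
    table["prop_down"] = table["n_down"] / table["n_total"]
    table["prop_up"] = table["n_up"] / table["n_total"]
    return table


def chisq_yates(table) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2x2 contingency table.

    ``chi2 = sum (|O - E| - 0.5)^2 / E`` with the continuity excess clipped
    so a cell never over-corrects past zero; p from the 1-df chi-square tail.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise EnrichmentError("chisq_yates expects a 2x2 table")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise EnrichmentError("table entries must be non-negative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise EnrichmentError("chi-square undefined: a table margin is zero")
    expected = np.outer(row, col) / obs.sum()
    excess = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float((excess**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


@dataclass
class EnrichmentTest:
    chromosome_class: str
    direction: str  # "down" or "up"
    n_regulated: int
    n_total: int
    n_regulated_autosome: int
    n_total_autosome: int
    chi2: float
    p: float
    deviation: str  # over / under / none
    stars: str
    low_power: bool


def run_enrichment(
    proportion_table: pd.DataFrame,
    reference_class: str = "Autosome",
    directions: tuple[str, ...] = ("down", "up"),
    exclude: tuple[str, ...] = ("Y", "Unplaced"),
) -> pd.DataFrame:
    """Each non-autosomal class vs autosomes, for down- and up-regulation.

    Classes with an undefined test (zero margin, e.g. no regulated gene in
    either class) are reported with NaN statistics and a warning rather than
    silently dropped.
    """
    if reference_class not in proportion_table.index:
        raise EnrichmentError(f"reference class {reference_class!r} absent from table")
    ref = proportion_table.loc[reference_class]
    results: list[EnrichmentTest] = []
    for chrom_class, row in proportion_table.iterrows():
        if chrom_class == reference_class or chrom_class in exclude:
            continue
        if row["n_total"] == 0:
            warnings.warn(f"class {chrom_class} has no annotated genes; skipped")
            continue
        for direction in directions:
            k_c, n_c = int(row[f"n_{direction}"]), int(row["n_total"])
            k_a, n_a = int(ref[f"n_{direction}"]), int(ref["n_total"])
            table = [[k_c, n_c - k_c], [k_a, n_a - k_a]]
            try:
                chi2, p = chisq_yates(table)
            except EnrichmentError as err:
                warnings.warn(f"{chrom_class} {direction}: {err}")
                chi2, p = np.nan, np.nan
            p_c, p_a = k_c / n_c, k_a / n_a
            deviation = "none"
            if np.isfinite(p) and p <= 0.05:
                deviation = "over" if p_c > p_a else "under"
            results.append(
                EnrichmentTest(
                    chromosome_class=str(chrom_class),
                    direction=direction,
                    n_regulated=k_c,
                    n_total=n_c,
                    n_regulated_autosome=k_a,
                    n_total_autosome=n_a,
                    chi2=chi2,
                    p=p,
                    deviation=deviation,
                    stars=stars(p),
                    low_power=n_c < LOW_POWER_MIN_TOTAL,
                )
            )
    return pd.DataFrame([r.__dict__ for r in results])


def positional_profile(
    gene_ids,
    annotation: pd.DataFrame,
    chromosome: str,
    n_bins: int = 50,
    chromosome_length: int | None = None,
) -> dict:
    """Binned positional distribution of a gene set along one chromosome.

    Gene midpoints are binned over [1, chromosome length] and compared with
    a uniform distribution by a one-sample KS test.  The uniformity test is
    this package's operationalization of "uniformly distributed along the
    chromosome" — the underlying observation is descriptive.
    """
    sub = annotation[annotation["chromosome_or_scaffold"] == chromosome]
    sub = sub.loc[sub.index.intersection(pd.Index(gene_ids))]
    if chromosome_length is None:
        full = annotation[annotation["chromosome_or_scaffold"] == chromosome]
        chromosome_length = int(full["end"].max()) if len(full) else 0
    if len(sub) == 0 or chromosome_length <= 0:
        return {
            "bins": pd.DataFrame(columns=["bin_start", "bin_end", "count"]),
            "ks_statistic": np.nan,
            "ks_p": np.nan,
            "n_genes": 0,
        }
    midpoints = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
    edges = np.linspace(1, chromosome_length, n_bins + 1)
    counts, _ = np.histogram(midpoints, bins=edges)
    bins = pd.DataFrame(
        {
            "bin_start": edges[:-1].round().astype(int),
            "bin_end": edges[1:].round().astype(int),
            "count": counts,
        }
    )
    ks = stats.kstest(midpoints, stats.uniform(loc=1, scale=chromosome_length - 1).cdf)
    return {
        "bins": bins,
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_genes": int(len(sub)),
    }
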