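"""Synthetic stage-enriched spermatogenesis RNA-seq generator.

Emulates the structure of testis-region bulk RNA-seq across the three
phases of Drosophila spermatogenesis: negative-binomial counts for genes on
chromosome classes {X, NeoX, Autosome, Dot, Y}, an MSCI effect (a configurable
fraction of X/NeoX genes fold-reduced during meiosis), gene-age classes with
their own stage trajectories, per-sample library-size factors, and
incomplete stage purity (each dissected region is a mixture of neighbouring
cell populations, modelled as a mixture of the pre-contamination stage means).

Every dataset carries a :class:`SyntheticTruth` with the generating
parameters resolved per gene, so parameter-recovery tests downstream never
have to re-derive what was simulated.

Model
-----
Per gene g with log2 baseline ``b_g ~ Normal(m, s)`` the pre-mixture mean in
stage t is ``mu0_gt = 2**(b_g + effect_gt)`` where ``effect_gt`` collects the
(class, age-group, stage) offset and, for MSCI-affected genes during meiosis,
the MSCI log2 fold-change.  Stage impurity blends these linearly:
``mu_gt = sum_u purity[t, u] * mu0_gu``.  Counts are drawn as
``NB(mean = sf_j * mu_gt, Var = mu + alpha * mu**2)`` (alpha = 0 degenerates
to Poisson).  Gene lengths are log-normal and used only to convert counts to
TPM; counts themselves are length-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .dataset import STAGES, TPM_SCALE, ExpressionDataset
from .de import compute_tpm

CHROM_CLASSES: tuple[str, ...] = ("X", "NeoX", "Autosome", "Dot", "Y")

#: class sizes shaped like a Drosophila melanogaster genome
#: (X ~ 15% of genes, dot ~ 0.6%, tiny Y; no neo-X by default)
DEFAULT_GENES_PER_CLASS: dict[str, int] = {
    "X": 1500,
    "NeoX": 0,
    "Autosome": 8350,
    "Dot": 60,
    "Y": 15,
}

#: dissected regions are enriched, not pure; neighbouring stages bleed in
DEFAULT_PURITY = (
    (0.85, 0.15, 0.00),
    (0.15, 0.70, 0.15),
    (0.00, 0.15, 0.85),
)

LN2 = np.log(2.0)


class ConfigurationError(ValueError):
    """Raised for simulation configs that violate their invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic staged experiment.

    ``stage_effects`` maps ``(chromosome_class, age_group, stage)`` to a log2
    offset added to the gene's baseline in that stage; missing keys mean 0.
    ``dispersion`` is either a constant NB dispersion alpha or a
    ``(mean, sd)`` pair on the natural-log scale (log-normal per-gene alpha).
    ``purity`` rows are mixture weights of each *observed* stage over the
    *true* stage means, in :data:`~mscikit.dataset.STAGES` order.
    """

    seed: int
    n_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CLASS)
    )
    n_replicates: int = 3
    stages: tuple[str, ...] = STAGES
    baseline_log2_mean_dist: tuple[float, float] = (5.0, 2.0)
    dispersion: float | tuple[float, float] = 0.1
    msci_fraction: float = 0.0
    msci_log2fc: float = 0.0
    stage_effects: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    age_new_fraction: float = 0.1
    library_size_dist: tuple[float, float] = (0.0, 0.2)
    purity: tuple[tuple[float, ...], ...] = DEFAULT_PURITY
    gene_length_dist: tuple[float, float] = (np.log(2000.0), 0.6)
    species: str = "synthetic"

    def validate(self) -> None:
        if tuple(self.stages) != STAGES:
            raise ConfigurationError(f"stages must be {STAGES}")
        if not 0.0 <= self.msci_fraction <= 1.0:
            raise ConfigurationError("msci_fraction must lie in [0, 1]")
        if not 0.0 <= self.age_new_fraction <= 1.0:
            raise ConfigurationError("age_new_fraction must lie in [0, 1]")
        if isinstance(self.dispersion, tuple):
            if self.dispersion[1] < 0:
                raise ConfigurationError("dispersion log-sd must be >= 0")
        elif self.dispersion < 0:
            raise ConfigurationError("dispersion alpha must be >= 0")
        for cls, n in self.n_genes_per_class.items():
            if cls not in CHROM_CLASSES:
                raise ConfigurationError(f"unknown chromosome class {cls!r}")
            if n < 0:
                raise ConfigurationError("gene counts per class must be >= 0")
        purity = np.asarray(self.purity, dtype=float)
        if purity.shape != (len(STAGES), len(STAGES)):
            raise ConfigurationError("purity must be a 3x3 stage-mixture matrix")
        if (purity < 0).any():
            raise ConfigurationError("purity weights must be non-negative")
        if not np.allclose(purity.sum(axis=1), 1.0, atol=1e-12):
            raise ConfigurationError("purity rows must each sum to 1")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate per stage")

    def purity_matrix(self) -> np.ndarray:
        return np.asarray(self.purity, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment.

    ``genes`` has one row per simulated gene: chromosome class, age group,
    whether the MSCI effect was applied, the true post-mixture log2
    fold-change (meiosis vs mitosis) and the expected normalized mean per
    stage.  ``size_factors`` are the true per-sample factors, and
    ``expected_xaa`` the analytic population X:AA (and NeoX:AA where
    applicable) ratio per stage under the config.
    """

    genes: pd.DataFrame
    size_factors: pd.Series
    expected_xaa: pd.DataFrame
    config: SimulationConfig


def null_config(seed: int, **overrides) -> SimulationConfig:
    """Global-null config: no MSCI, no stage effects, identity purity.

    Under this config no gene's expected expression depends on stage, which
    is the null hypothesis of every downstream calibration test.
    """
    cfg = SimulationConfig(
        seed=seed,
        msci_fraction=0.0,
        msci_log2fc=0.0,
        stage_effects={},
        purity=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
    )
    return replace(cfg, **overrides)


def msci_config(
    seed: int,
    msci_fraction: float = 0.5,
    msci_log2fc: float = -1.0,
    **overrides,
) -> SimulationConfig:
    """MSCI scenario: a fraction of X/NeoX genes fold-reduced in meiosis."""
    cfg = SimulationConfig(
        seed=seed, msci_fraction=msci_fraction, msci_log2fc=msci_log2fc
    )
    return replace(cfg, **overrides)


def age_dynamics_config(seed: int, newx_log2: float = 1.0, **overrides) -> SimulationConfig:
    """Age-trajectory scenario mirroring the observed Drosophila pattern.

    New X-linked genes carry a constant +``newx_log2`` offset, so after the
    purity mixture their observed mean stays elevated at every stage; new
    autosomal genes start flat and rise toward post-meiosis.  The autosomal
    post-meiotic (pre-mixture) offset is solved from the purity matrix so
    that the *observed* post-meiotic means of new X and new autosomal genes
    coincide exactly — post-meiotic convergence is null by construction.
    """
    base = SimulationConfig(seed=seed, age_new_fraction=0.3)
    cfg = replace(base, **{k: v for k, v in overrides.items() if k != "stage_effects"})
    purity = cfg.purity_matrix()
    pm = STAGES.index("post_meiosis")
    a_mit, a_mei = 0.0, newx_log2 / 2.0
    # observed post-meiotic A mean must equal the X one (2**newx_log2):
    # purity[pm] . (2**a_mit, 2**a_mei, 2**a_pm) = 2**newx_log2
    resid = 2.0**newx_log2 - purity[pm, 0] * 2.0**a_mit - purity[pm, 1] * 2.0**a_mei
    if resid <= 0 or purity[pm, pm] <= 0:
        raise ConfigurationError("purity matrix incompatible with convergence scenario")
    a_pm = float(np.log2(resid / purity[pm, pm]))
    effects = {
        ("X", "new", "mitosis"): newx_log2,
        ("X", "new", "meiosis"): newx_log2,
        ("X", "new", "post_meiosis"): newx_log2,
        ("Autosome", "new", "mitosis"): a_mit,
        ("Autosome", "new", "meiosis"): a_mei,
        ("Autosome", "new", "post_meiosis"): a_pm,
    }
    return replace(cfg, stage_effects=dict(effects))


# ---------------------------------------------------------------------------
# simulation


def _gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene static attributes: class, age, MSCI membership, baseline."""
    classes: list[str] = []
    for cls in CHROM_CLASSES:
        classes.extend([cls] * int(config.n_genes_per_class.get(cls, 0)))
    n = len(classes)
    if n == 0:
        raise ConfigurationError("config generates zero genes")
    gene_ids = [f"g{i:06d}" for i in range(n)]
    m, s = config.baseline_log2_mean_dist
    baseline = rng.normal(m, s, size=n)
    is_new = rng.random(n) < config.age_new_fraction
    age_branch = np.where(is_new, rng.integers(1, 7, size=n), 0)
    cls_arr = np.asarray(classes)
    on_sex = np.isin(cls_arr, ("X", "NeoX"))
    msci_affected = on_sex & (rng.random(n) < config.msci_fraction)
    if isinstance(config.dispersion, tuple):
        mu_log, sd_log = config.dispersion
        alpha = np.exp(rng.normal(mu_log, sd_log, size=n))
    else:
        alpha = np.full(n, float(config.dispersion))
    lengths = np.exp(rng.normal(*config.gene_length_dist, size=n))
    lengths = np.maximum(lengths, 100.0).round().astype(int)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome_class": cls_arr,
            "age_branch": age_branch,
            "age_group": np.where(is_new, "new", "old"),
            "msci_affected": msci_affected,
            "baseline_log2": baseline,
            "dispersion": alpha,
            "length": lengths,
        }
    ).set_index("gene_id")


def _stage_offsets(config: SimulationConfig, genes: pd.DataFrame) -> np.ndarray:
    """Per-gene x per-stage log2 offsets (stage effects + MSCI), pre-mixture."""
    n = len(genes)
    offsets = np.zeros((n, len(STAGES)))
    eff = dict(config.stage_effects)
    if eff:
        for t, stage in enumerate(STAGES):
            key_vals = [
                eff.get((c, a, stage), 0.0)
                for c, a in zip(genes["chromosome_class"], genes["age_group"])
            ]
            offsets[:, t] += np.asarray(key_vals)
    mei = STAGES.index("meiosis")
    offsets[genes["msci_affected"].to_numpy(), mei] += config.msci_log2fc
    return offsets


def _expected_means(config: SimulationConfig, genes: pd.DataFrame) -> np.ndarray:
    """Post-mixture expected normalized mean, genes x stages."""
    mu0 = 2.0 ** (genes["baseline_log2"].to_numpy()[:, None] + _stage_offsets(config, genes))
    return mu0 @ config.purity_matrix().T


def _draw_counts(
    mu: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean=mu, Var=mu+alpha*mu^2) draws; alpha = 0 falls back to Poisson."""
    lam = np.array(mu, dtype=float)
    over = alpha > 0
    if over.any():
        a = alpha[over][:, None] if alpha.ndim == 1 else alpha[over]
        shape = 1.0 / a
        lam_over = rng.gamma(shape=np.broadcast_to(shape, lam[over].shape), scale=a * mu[over])
        lam[over] = lam_over
    return rng.poisson(lam)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.DataFrame, SyntheticTruth]:
    """Draw one staged experiment and its ground truth.

    Returns ``(dataset, annotation, truth)``.  The annotation table has the
    standard per-gene fields (synthetic coordinates on one contig per
    chromosome class, Muller element consistent with a melanogaster-like
    karyotype, biotype ``coding``).  Identical config (including seed) gives
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config, rng)
    expected = _expected_means(config, genes)  # genes x stages

    n_samples = len(STAGES) * config.n_replicates
    sf = np.exp(rng.normal(*config.library_size_dist, size=n_samples))
    sample_ids, stages_per_sample = [], []
    for stage in STAGES:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{stage}_r{r}")
            stages_per_sample.append(stage)
    alpha = genes["dispersion"].to_numpy()

    count_cols = {}
    for j, (sid, stage) in enumerate(zip(sample_ids, stages_per_sample)):
        mu_j = sf[j] * expected[:, STAGES.index(stage)]
        count_cols[sid] = _draw_counts(mu_j[:, None], alpha, rng)[:, 0]
    counts = pd.DataFrame(count_cols, index=genes.index)

    lengths = genes["length"]
    tpm = compute_tpm(counts, lengths)
    samples = pd.DataFrame(
        {
            "species": config.species,
            "stage": stages_per_sample,
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    dataset = ExpressionDataset(counts=counts, tpm=tpm, samples=samples)

    annotation = _make_annotation(genes)
    truth = _make_truth(config, genes, expected, pd.Series(sf, index=sample_ids))
    return dataset, annotation, truth


_CLASS_TO_MULLER = {"X": "A", "NeoX": "D", "Autosome": "E", "Dot": "F", "Y": "unknown"}
_CLASS_TO_CONTIG = {
    "X": "chrX",
    "NeoX": "chrNeoX",
    "Autosome": "chrA",
    "Dot": "chrDot",
    "Y": "chrY",
}


def _make_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Synthetic gene annotation laid out gene-after-gene along one contig
    per chromosome class (1-based inclusive coordinates)."""
    rows = []
    cursor: dict[str, int] = {c: 1 for c in CHROM_CLASSES}
    for gid, row in genes.iterrows():
        cls = row["chromosome_class"]
        start = cursor[cls]
        end = start + int(row["length"]) - 1
        cursor[cls] = end + 1000  # fixed intergenic spacing
        rows.append(
            {
                "gene_id": gid,
                "chromosome_or_scaffold": _CLASS_TO_CONTIG[cls],
                "start": start,
                "end": end,
                "strand": "+",
                "muller_element": _CLASS_TO_MULLER[cls],
                "chromosome_class": cls,
                "biotype": "coding",
                "length": int(row["length"]),
                "age_branch": int(row["age_branch"]),
                "n_transcripts": 1,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _make_truth(
    config: SimulationConfig,
    genes: pd.DataFrame,
    expected: np.ndarray,
    size_factors: pd.Series,
) -> SyntheticTruth:
    mit, mei = STAGES.index("mitosis"), STAGES.index("meiosis")
    truth_genes = genes[
        ["chromosome_class", "age_group", "age_branch", "msci_affected", "dispersion"]
    ].copy()
    truth_genes["true_log2fc_meiosis_vs_mitosis"] = np.log2(
        expected[:, mei] / expected[:, mit]
    )
    for t, stage in enumerate(STAGES):
        truth_genes[f"expected_mean_{stage}"] = expected[:, t]
    expected_xaa = analytic_expectations(config)["xaa"]
    return SyntheticTruth(
        genes=truth_genes,
        size_factors=size_factors,
        expected_xaa=expected_xaa,
        config=config,
    )


# ---------------------------------------------------------------------------
# closed-form expectations


def _class_components(
    config: SimulationConfig, cls: str, stage_idx: int
) -> list[tuple[float, float]]:
    """Mixture components of a class's post-mixture expected expression.

    Within a chromosome class the population of per-gene expected means at an
    observed stage is a finite mixture of log-normals sharing the baseline
    log2-sd: gene subgroups (age group x MSCI membership) differ only by a
    multiplicative constant ``c = sum_u purity[t, u] * 2**offset_u``.  Returns
    ``(weight, log2 c)`` pairs.
    """
    purity = config.purity_matrix()[stage_idx]
    eff = dict(config.stage_effects)
    comps: list[tuple[float, float]] = []
    w_new = config.age_new_fraction
    on_sex = cls in ("X", "NeoX")
    mei = STAGES.index("meiosis")
    for age, w_age in (("old", 1.0 - w_new), ("new", w_new)):
        base_off = np.array([eff.get((cls, age, s), 0.0) for s in STAGES])
        branches = [(1.0, 0.0)]
        if on_sex and config.msci_fraction > 0:
            branches = [
                (1.0 - config.msci_fraction, 0.0),
                (config.msci_fraction, config.msci_log2fc),
            ]
        for w_b, msci_off in branches:
            off = base_off.copy()
            off[mei] += msci_off
            c = float(purity @ (2.0**off))
            w = w_age * w_b
            if w > 0:
                comps.append((w, np.log2(c)))
    return comps


def _mixture_median_log2(
    comps: list[tuple[float, float]], m: float, s: float
) -> float:
    """Median (in log2 units) of a mixture of Normal(m + shift_k, s)."""
    locs = [m + shift for _, shift in comps]
    if s == 0:
        # degenerate: weighted discrete distribution
        pts = sorted(zip(locs, (w for w, _ in comps)))
        acc = 0.0
        for x, w in pts:
            acc += w
            if acc >= 0.5:
                return x
        return pts[-1][0]
    lo, hi = min(locs) - 10 * s, max(locs) + 10 * s

    def cdf(x: float) -> float:
        return sum(w * norm.cdf(x, loc=m + shift, scale=s) for w, shift in comps) - 0.5

    return brentq(cdf, lo, hi, xtol=1e-12)


def analytic_expectations(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Closed-form population expectations implied by a config.

    Returns ``{"class_means": ..., "xaa": ...}`` where ``class_means`` gives
    the expected normalized mean per (chromosome class, stage), averaging
    over the baseline distribution and gene subgroups, and ``xaa`` gives the
    population X:AA (and NeoX:AA when the config has NeoX genes) ratio of
    class medians per stage — the recovery target of the threshold-0
    filter-by-fraction estimator.
    """
    config.validate()
    m, s = config.baseline_log2_mean_dist
    e_base = np.exp(m * LN2 + 0.5 * (s * LN2) ** 2)  # E[2**b]
    mean_rows, med = {}, {}
    for cls in CHROM_CLASSES:
        if config.n_genes_per_class.get(cls, 0) <= 0:
            continue
        means, medians = [], []
        for t in range(len(STAGES)):
            comps = _class_components(config, cls, t)
            means.append(e_base * sum(w * 2.0**shift for w, shift in comps))
            medians.append(2.0 ** _mixture_median_log2(comps, m, s))
        mean_rows[cls] = means
        med[cls] = medians
    class_means = pd.DataFrame(mean_rows, index=list(STAGES)).T
    class_means.index.name = "chromosome_class"

    xaa_rows = {}
    if "Autosome" in med:
        for num in ("X", "NeoX"):
            if num in med:
                xaa_rows[num] = [
                    med[num][t] / med["Autosome"][t] for t in range(len(STAGES))
                ]
    xaa = pd.DataFrame(xaa_rows, index=list(STAGES)).T
    xaa.index.name = "numerator_class"
    return {"class_means": class_means, "xaa": xaa}
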