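"""End-to-end MSCI analysis pipeline.

One config drives the whole chain: (optionally) simulate a staged dataset,
run the meiosis-vs-mitosis and post-meiosis-vs-meiosis NB Wald contrasts,
test chromosomal enrichment of the regulated classes, estimate per-stage
X:AA ratios by both estimators, compute age-stratified trajectories and
contrasts, cluster stage profiles, and write every table plus a
machine-readable report and a checksum manifest.  Reruns with the same
config (and seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .age import compare_age_location_groups, stage_trajectories
from .dataset import ExpressionDataset
from .de import DEFAULT_Q_THRESHOLD, stage_contrast
from .enrichment import run_enrichment, tabulate_class_counts
from .profiles import DEFAULT_K, kmeans_profiles, zscore_stage_profile
from .synthetic import SimulationConfig, simulate_experiment
from .xaa import DEFAULT_THRESHOLDS, stage_ratio_comparison, xaa_table
from .age import per_gene_stage_values

log = logging.getLogger("mscikit.pipeline")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run.

    Exactly one of ``simulation`` or (``dataset_dir`` + ``annotation_path``)
    must be provided.
    """

    outdir: str | Path
    seed: int
    simulation: SimulationConfig | None = None
    dataset_dir: str | Path | None = None
    annotation_path: str | Path | None = None
    contrasts: tuple[tuple[str, str], ...] = (
        ("meiosis", "mitosis"),
        ("post_meiosis", "meiosis"),
    )
    q_threshold: float = DEFAULT_Q_THRESHOLD
    tpm_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    k_clusters: int = DEFAULT_K
    biotype: str = "coding"

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_real = self.dataset_dir is not None and self.annotation_path is not None
        if has_sim == has_real:
            raise PipelineError(
                "provide exactly one of a simulation config or dataset+annotation paths"
            )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        _write_tsv(df, path, **kw)
        written.append(path)

    # -- input ---------------------------------------------------------------
    if config.simulation is not None:
        log.info("[simulate] drawing synthetic experiment (seed=%d)", config.simulation.seed)
        dataset, annotation, truth = simulate_experiment(config.simulation)
        emit(dataset.counts, "counts.tsv", index_label="gene_id")
        emit(dataset.tpm, "tpm.tsv", index_label="gene_id")
        emit(dataset.samples, "samples.tsv", index_label="sample_id")
        emit(annotation, "annotation.tsv", index_label="gene_id")
        emit(truth.genes, "truth_genes.tsv", index_label="gene_id")
    else:
        log.info("[load] reading dataset from %s", config.dataset_dir)
        dataset = ExpressionDataset.from_dir(config.dataset_dir)
        annotation = pd.read_csv(config.annotation_path, sep="\t", index_col="gene_id")

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_genes": int(len(dataset.gene_ids)),
        "n_samples": int(len(dataset.samples)),
    }

    # -- differential expression + enrichment --------------------------------
    enrich_summary = {}
    for numerator, denominator in config.contrasts:
        name = f"{numerator}_vs_{denominator}"
        log.info("[de] contrast %s", name)
        try:
            de = stage_contrast(dataset, numerator, denominator, q_threshold=config.q_threshold)
        except Exception as err:  # noqa: BLE001 - abort with stage context
            raise PipelineError(f"stage de ({name}) failed: {err}") from err
        emit(de, f"de_{name}.tsv", index_label="gene_id")

        log.info("[enrich] contrast %s", name)
        table = tabulate_class_counts(de["class"], annotation, biotype=config.biotype)
        emit(table, f"class_counts_{name}.tsv")
        enr = run_enrichment(table)
        emit(enr, f"enrichment_{name}.tsv", index=False)
        enrich_summary[name] = {
            "class_counts": json.loads(table.to_json(orient="index")),
            "tests": json.loads(enr.to_json(orient="records")),
        }
    report["enrichment"] = enrich_summary

    # -- X:AA ratios ----------------------------------------------------------
    log.info("[xaa] per-stage expression ratios")
    try:
        xaa = xaa_table(dataset, annotation, thresholds=config.tpm_thresholds)
        emit(xaa, "xaa.tsv", index=False)
        comparison = stage_ratio_comparison(xaa)
        emit(comparison, "xaa_stage_tests.tsv", index=False)
        pooled = xaa[(xaa["replicate"] == "pooled") & xaa["defined"]]
        report["xaa_pooled"] = json.loads(pooled.to_json(orient="records"))
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage xaa failed: {err}") from err

    # -- age dynamics ---------------------------------------------------------
    log.info("[age] trajectories and contrasts")
    try:
        traj = stage_trajectories(dataset, annotation)
        emit(traj, "age_trajectories.tsv", index=False)
        contrasts = compare_age_location_groups(dataset, annotation)
        emit(contrasts, "age_contrasts.tsv", index=False)
        report["age_contrasts"] = json.loads(contrasts.to_json(orient="records"))
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage age failed: {err}") from err

    # -- profile clustering ---------------------------------------------------
    log.info("[cluster] k-means stage profiles (k=%d)", config.k_clusters)
    try:
        stage_means = per_gene_stage_values(dataset)
        profiles, excluded = zscore_stage_profile(stage_means)
        clustering = kmeans_profiles(profiles, k=config.k_clusters, seed=config.seed)
        emit(clustering.labels.to_frame(), "clusters.tsv", index_label="gene_id")
        emit(clustering.centroids, "cluster_centroids.tsv", index_label="cluster")
        report["clusters"] = {
            "k": clustering.k,
            "proportions": {int(c): float(p) for c, p in clustering.proportions.items()},
            "n_excluded_flat_profiles": int(len(excluded)),
        }
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage cluster failed: {err}") from err

    # -- report + manifest ----------------------------------------------------
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, allow_nan=True))
    written.append(report_path)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config from a YAML file (keys = field names)."""
    raw = yaml.safe_load(Path(path).read_text())
    if "stage_effects" in raw:
        raw["stage_effects"] = {
            tuple(k.split("/")): float(v) for k, v in raw["stage_effects"].items()
        }
    for key in ("baseline_log2_mean_dist", "library_size_dist", "gene_length_dist"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "purity" in raw:
        raw["purity"] = tuple(tuple(row) for row in raw["purity"])
    if isinstance(raw.get("dispersion"), list):
        raw["dispersion"] = tuple(raw["dispersion"])
    return SimulationConfig(**raw)
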