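"""Core data containers for stage-enriched spermatogenesis expression data.

The pipeline operates on a single input bundle: a gene-by-sample integer
count matrix, the matching TPM matrix, and a sample sheet giving species,
spermatogenesis stage and replicate for every sample.  Stages are the three
classical phases of Drosophila spermatogenesis captured by testis-region
dissection: mitosis (spermatogonia), meiosis (spermatocytes) and
post-meiosis (spermatids).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

STAGES: tuple[str, ...] = ("mitosis", "meiosis", "post_meiosis")

#: accepted spellings for each canonical stage label
_STAGE_ALIASES = {
    "mitosis": "mitosis",
    "mit": "mitosis",
    "meiosis": "meiosis",
    "mei": "meiosis",
    "post_meiosis": "post_meiosis",
    "post-meiosis": "post_meiosis",
    "postmeiosis": "post_meiosis",
    "pm": "post_meiosis",
}

TPM_SCALE = 1e6


class ValidationError(ValueError):
    """Raised when an input bundle violates its structural contract."""


def canonical_stage(stage: str) -> str:
    """Map a stage spelling (e.g. ``"post-meiosis"``) to its canonical token."""
    try:
        return _STAGE_ALIASES[str(stage).strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown spermatogenesis stage {stage!r}; expected one of {STAGES}"
        ) from None


@dataclass
class ExpressionDataset:
    """Counts + TPM + sample sheet for one species' staged transcriptomes.

    Attributes
    ----------
    counts : DataFrame, genes x samples, non-negative integers.
    tpm : DataFrame, genes x samples; every column sums to 1e6.
    samples : DataFrame indexed by sample id with columns
        ``species``, ``stage`` (canonical), ``replicate``.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.copy()
        self.samples["stage"] = [canonical_stage(s) for s in self.samples["stage"]]
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValidationError("count columns do not match the sample sheet")
        if list(self.tpm.columns) != list(self.samples.index):
            raise ValidationError("tpm columns do not match the sample sheet")
        if not self.counts.index.equals(self.tpm.index):
            raise ValidationError("counts and tpm index different gene sets")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative entries in the count matrix")
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("negative entries in the TPM matrix")
        colsums = self.tpm.to_numpy(dtype=float).sum(axis=0)
        if not np.allclose(colsums, TPM_SCALE, rtol=1e-6):
            raise ValidationError("TPM columns must each sum to 1e6")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def stage_samples(self, stage: str) -> list[str]:
        """Sample ids belonging to one stage, in sheet order."""
        stage = canonical_stage(stage)
        return list(self.samples.index[self.samples["stage"] == stage])

    def stages_present(self) -> list[str]:
        return [s for s in STAGES if (self.samples["stage"] == s).any()]

    # -- plain-text round trip -------------------------------------------------

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
        self.tpm.to_csv(
            outdir / "tpm.tsv", sep="\t", index_label="gene_id", float_format="%.10g"
        )
        self.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample_id")

    @classmethod
    def from_dir(cls, indir: str | Path) -> "ExpressionDataset":
        indir = Path(indir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="gene_id")
        tpm = pd.read_csv(indir / "tpm.tsv", sep="\t", index_col="gene_id")
        samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample_id")
        return cls(counts=counts, tpm=tpm, samples=samples)
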