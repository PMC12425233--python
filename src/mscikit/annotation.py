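"""Chromosome-class assignment, gene-age grouping and ortholog filtering.

Drosophila chromosome arms are conserved Muller elements A-F whose linkage
is preserved across the genus: element A is the X and F the dot chromosome
in D. melanogaster.  D. willistoni carries two fusions — Muller D is fused
to the X (a neo-X) and the ancestral dot (F) is fused to the E element, so
its dot genes live on an E-element scaffold on one side of a known junction.
Species schemes encode the element-to-class map plus any such fusion rule.

Gene ages are phylogenetic branches of origin: branch 0 predates the
Sophophora/Drosophila split ("old"); branches 1-6 are younger ("new",
< 62 My, with 6 = melanogaster-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")

CHROMOSOME_CLASSES = ("X", "NeoX", "Autosome", "Dot", "Y", "Unplaced")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class FusionRule:
    """Scaffold-level override for a chromosomal fusion.

    Genes on ``scaffold`` whose start falls on the dot side of
    ``junction`` (strictly below it when ``dot_side == "below"``, at or
    above it otherwise) are classified ``Dot`` regardless of their Muller
    element.  Which side of the willistoni E-F junction holds the dot genes
    is a configuration choice; below-the-junction is the default.
    """

    scaffold: str
    junction: int
    dot_side: str = "below"

    def applies(self, scaffold: str) -> bool:
        return scaffold == self.scaffold

    def is_dot(self, start: int) -> bool:
        if self.dot_side == "below":
            return start < self.junction
        return start >= self.junction


@dataclass(frozen=True)
class SpeciesScheme:
    """Per-species mapping from Muller elements to chromosome classes."""

    species: str
    element_to_class: Mapping[str, str]
    fusion: FusionRule | None = None
    y_chromosomes: tuple[str, ...] = ("Y", "chrY")

    def __post_init__(self) -> None:
        missing = [e for e in MULLER_ELEMENTS if e not in self.element_to_class]
        if missing:
            raise AnnotationError(
                f"scheme for {self.species} lacks Muller element(s) {missing}"
            )

    @property
    def autosome_elements(self) -> tuple[str, ...]:
        return tuple(
            e for e in MULLER_ELEMENTS if self.element_to_class[e] == "Autosome"
        )


_STANDARD_MAP = {
    "A": "X",
    "B": "Autosome",
    "C": "Autosome",
    "D": "Autosome",
    "E": "Autosome",
    "F": "Dot",
}

MELANOGASTER = SpeciesScheme("D. melanogaster", dict(_STANDARD_MAP))
SIMULANS = SpeciesScheme("D. simulans", dict(_STANDARD_MAP))
MOJAVENSIS = SpeciesScheme("D. mojavensis", dict(_STANDARD_MAP))

#: willistoni: Muller D fused to the X (neo-X); ancestral dot fused into the
#: E-element scaffold, junction region 2,014,728-2,029,101 between the
#: F-side and E-side marker genes
WILLISTONI_EF_SCAFFOLD = "scf2_1100000004943"
WILLISTONI_EF_JUNCTION = 2_014_728
WILLISTONI = SpeciesScheme(
    "D. willistoni",
    {**_STANDARD_MAP, "D": "NeoX"},
    fusion=FusionRule(WILLISTONI_EF_SCAFFOLD, WILLISTONI_EF_JUNCTION),
)

SCHEMES = {
    "melanogaster": MELANOGASTER,
    "simulans": SIMULANS,
    "mojavensis": MOJAVENSIS,
    "willistoni": WILLISTONI,
}


def classify_chromosome(gene, scheme: SpeciesScheme) -> str:
    """Chromosome class of one gene record under a species scheme.

    ``gene`` is any mapping (dict, Series, dataclass-asdict) exposing
    ``chromosome_or_scaffold``, ``muller_element`` and ``start``.  The fusion
    rule takes precedence over the element map; Y scaffolds are ``Y``;
    anything the scheme cannot place is ``Unplaced`` (never a silent guess).
    """
    get = gene.get if hasattr(gene, "get") else lambda k, d=None: getattr(gene, k, d)
    scaffold = str(get("chromosome_or_scaffold", ""))
    element = str(get("muller_element", "unknown"))
    if scaffold in scheme.y_chromosomes:
        return "Y"
    if scheme.fusion is not None and scheme.fusion.applies(scaffold):
        start = int(get("start"))
        if scheme.fusion.is_dot(start):
            return "Dot"
        # non-dot side falls back to the element mapping below
    if element in scheme.element_to_class:
        return scheme.element_to_class[element]
    return "Unplaced"


def classify_table(annotation: pd.DataFrame, scheme: SpeciesScheme) -> pd.Series:
    """Vectorised :func:`classify_chromosome` over an annotation table."""
    return pd.Series(
        [classify_chromosome(row, scheme) for _, row in annotation.iterrows()],
        index=annotation.index,
        name="chromosome_class",
    )


def assign_age_group(age_branch) -> str:
    """Map a phylogenetic age branch to {old, new, unknown}.

    Branch 0 (predating the Sophophora/Drosophila split) is old; branches
    1-6 are new; a missing branch is unknown and excluded from age analyses.
    """
    if age_branch is None or (isinstance(age_branch, float) and pd.isna(age_branch)):
        return "unknown"
    branch = int(age_branch)
    if branch == 0:
        return "old"
    if 1 <= branch <= 6:
        return "new"
    raise AnnotationError(f"age branch {branch} outside the valid range 0-6")


def filter_orthologs(
    ortholog_table: pd.DataFrame,
    annotations: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the stringent cross-species ortholog filter.

    ``ortholog_table`` has one column per species holding that species' gene
    id; ``annotations`` maps species to a gene-id-indexed table with
    ``n_transcripts``, ``muller_element`` and ``chromosome_class``.

    A tuple is retained iff (1) every member has exactly one annotated
    transcript, (2) all members share a Muller element, and (3) no member is
    Y-linked or sits on Muller D (a neo-X in willistoni, an autosome
    elsewhere — removing the whole tuple keeps the ortholog set consistent
    across species).  A tuple failing several criteria is counted once,
    under the first in (1) -> (2) -> (3) order.

    Returns the retained subset and per-criterion rejection counts.
    """
    species = list(ortholog_table.columns)
    lookup = {}
    for sp in species:
        ann = annotations[sp]
        missing = set(ortholog_table[sp]) - set(ann.index)
        if missing:
            raise AnnotationError(
                f"ortholog ids not found in {sp} annotation: {sorted(missing)[:10]}"
            )
        lookup[sp] = ann

    rejections = {"multi_transcript": 0, "element_mismatch": 0, "y_or_mullerD": 0}
    keep = []
    for idx, row in ortholog_table.iterrows():
        members = [(sp, lookup[sp].loc[row[sp]]) for sp in species]
        if any(int(m["n_transcripts"]) != 1 for _, m in members):
            rejections["multi_transcript"] += 1
            continue
        elements = {str(m["muller_element"]) for _, m in members}
        if len(elements) != 1:
            rejections["element_mismatch"] += 1
            continue
        element = elements.pop()
        on_y = any(str(m["chromosome_class"]) == "Y" for _, m in members)
        if on_y or element == "D":
            rejections["y_or_mullerD"] += 1
            continue
        keep.append(idx)
    return ortholog_table.loc[keep], rejections


def read_annotation(path) -> pd.DataFrame:
    """Read an annotation TSV (gene_id-indexed, 1-based inclusive coords)."""
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"chromosome_class", "biotype", "length"}
    missing = required - set(ann.columns)
    if missing:
        raise AnnotationError(f"annotation table lacks columns {sorted(missing)}")
    if {"start", "end"} <= set(ann.columns) and (ann["start"] > ann["end"]).any():
        raise AnnotationError("annotation has start > end (coordinates are 1-based inclusive)")
    return ann
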