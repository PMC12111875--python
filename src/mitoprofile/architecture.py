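"""Genome-architecture statistics of an annotated mitogenome.

Computes per-class gene counts and lengths, strand usage, the signed
circular gene order, and the intergenic spacers / overlaps between
consecutive features.  The gap between start-sorted neighbors *i*, *j* is
``start(j) - end(i) - 1`` (positive = spacer, negative = overlap, zero =
abutting); on circular genomes a final record closes the circle, so that

    sum(feature lengths) + sum(signed gaps) == genome_length

holds exactly whenever no feature wraps the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._util import round_half_up
from .annotation_io import GenomeAnnotation
from .rearrangement import GeneOrder

__all__ = ["GapRecord", "ArchitectureSummary", "gene_order",
           "intergenic_gaps", "summarize_architecture"]


@dataclass(frozen=True)
class GapRecord:
    """Signed gap between two features adjacent on the (circular) genome."""

    upstream_feature: str
    downstream_feature: str
    gap: int

    @property
    def kind(self) -> str:
        if self.gap > 0:
            return "spacer"
        if self.gap < 0:
            return "overlap"
        return "abutting"


@dataclass
class ArchitectureSummary:
    genome_length: int
    class_counts: dict[str, int]
    class_bp: dict[str, int]
    class_percent: dict[str, float]
    plus_strand_genes: int
    minus_strand_genes: int
    spacer_total_bp: int
    spacer_regions: int
    overlap_total_bp: int
    overlap_regions: int
    largest_spacers: list[GapRecord] = field(default_factory=list)


def gene_order(ann: GenomeAnnotation, anchor: str,
               label: str = "genome") -> GeneOrder:
    """Signed circular gene order, start-sorted and rotated to ``anchor``.

    The result is invariant under rotation of the genome coordinates.
    """
    feats = ann.sorted_features()
    if not feats:
        raise ValueError("annotation has no features")
    names = [f.name for f in feats]
    if anchor not in names:
        raise ValueError(f"anchor gene {anchor!r} not present in annotation")
    i = names.index(anchor)
    rotated = feats[i:] + feats[:i]
    return GeneOrder(label=label,
                     genes=tuple((f.name, 1 if f.strand == "+" else -1)
                                 for f in rotated))


def intergenic_gaps(ann: GenomeAnnotation) -> list[GapRecord]:
    """Signed gaps between consecutive start-sorted features.

    Circular genomes get one record per feature (the last wraps the
    origin); linear genomes get ``n - 1`` records.
    """
    feats = ann.sorted_features()
    if len(feats) < 2:
        raise ValueError("need at least 2 features to compute gaps")
    records = []
    for up, down in zip(feats, feats[1:]):
        records.append(GapRecord(up.name, down.name,
                                 down.start - up.end - 1))
    if ann.topology == "circular":
        last, first = feats[-1], feats[0]
        wrap = (ann.genome_length - last.end) + (first.start - 1)
        records.append(GapRecord(last.name, first.name, wrap))
    return records


def summarize_architecture(ann: GenomeAnnotation,
                           top_spacers: int = 3) -> ArchitectureSummary:
    """Class totals, strand usage and spacer/overlap statistics."""
    feats = ann.features
    class_counts: dict[str, int] = {}
    class_bp: dict[str, int] = {}
    for f in feats:
        class_counts[f.feature_class] = class_counts.get(f.feature_class, 0) + 1
        class_bp[f.feature_class] = class_bp.get(f.feature_class, 0) + f.length
    class_percent = {c: round_half_up(100.0 * bp / ann.genome_length, 2)
                     for c, bp in class_bp.items()}
    gaps = intergenic_gaps(ann) if len(feats) >= 2 else []
    spacers = [g for g in gaps if g.gap > 0]
    overlaps = [g for g in gaps if g.gap < 0]
    # rank strictly by gap size; ties keep upstream genome order
    ranked = sorted(spacers, key=lambda g: -g.gap)
    return ArchitectureSummary(
        genome_length=ann.genome_length,
        class_counts=class_counts,
        class_bp=class_bp,
        class_percent=class_percent,
        plus_strand_genes=sum(1 for f in feats if f.strand == "+"),
        minus_strand_genes=sum(1 for f in feats if f.strand == "-"),
        spacer_total_bp=sum(g.gap for g in spacers),
        spacer_regions=len(spacers),
        overlap_total_bp=sum(-g.gap for g in overlaps),
        overlap_regions=len(overlaps),
        largest_spacers=ranked[:top_spacers],
    )
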