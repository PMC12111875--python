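"""Pipeline orchestration: run the analysis stages and emit TSV reports.

Reports are deterministic: fixed column order, one header line, rounding
applied only here (percentages to 2 decimals, skews to 3, RSCU to 2), with
full-precision values duplicated in a machine-readable ``summary.json``.
Stages that lack their inputs (composition/codons/tRNA need a sequence)
are skipped with a notice rather than failing.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ._util import round_half_up
from . import architecture as arch
from . import codon_usage as cu
from . import composition as comp
from . import rearrangement as rearr
from . import trna_structure as trna
from .annotation_io import GenomeAnnotation, read_annotation, read_fasta

logger = logging.getLogger("mitoprofile")

__all__ = ["RunConfig", "run_profile", "run_compare", "read_gene_orders",
           "write_gene_orders"]


@dataclass
class RunConfig:
    annotation_path: str
    outdir: str
    annotation_format: str = "tsv"
    fasta_path: Optional[str] = None
    code_id: int = 5
    family_mode: str = "code_families"
    anchor: Optional[str] = None
    stages: tuple[str, ...] = ("architecture", "composition", "codons", "trna")
    log_level: str = "INFO"


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def _fmt(x: Optional[float], nd: int) -> Optional[float]:
    return None if x is None else round_half_up(x, nd)


def run_profile(config: RunConfig) -> dict:
    """Run the requested stages; returns the raw machine-readable summary."""
    logging.basicConfig(level=config.log_level)
    ann = read_annotation(config.annotation_path, format=config.annotation_format)
    if ann.sequence is None and config.fasta_path:
        ann.sequence = read_fasta(config.fasta_path,
                                  expected_length=ann.genome_length)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"genome_length": ann.genome_length,
                     "topology": ann.topology, "stages": []}

    if "architecture" in config.stages:
        summary["architecture"] = _stage_architecture(ann, config, outdir)
        summary["stages"].append("architecture")

    seq_stages = [s for s in ("composition", "codons", "trna")
                  if s in config.stages]
    if seq_stages and ann.sequence is None:
        logger.info("no sequence available; skipping stages: %s",
                    ", ".join(seq_stages))
    elif seq_stages:
        if "composition" in seq_stages:
            summary["composition"] = _stage_composition(ann, outdir)
            summary["stages"].append("composition")
        if "codons" in seq_stages:
            summary["codons"] = _stage_codons(ann, config, outdir)
            summary["stages"].append("codons")
        if "trna" in seq_stages:
            summary["trna"] = _stage_trna(ann, outdir)
            summary["stages"].append("trna")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _stage_architecture(ann: GenomeAnnotation, config: RunConfig,
                        outdir: Path) -> dict:
    feats = ann.sorted_features()
    gaps = arch.intergenic_gaps(ann) if len(feats) >= 2 else []
    gap_after = {g.upstream_feature: g.gap for g in gaps}
    _write_tsv(outdir / "architecture.tsv",
               ["name", "class", "start", "end", "length", "strand",
                "anticodon", "start_codon", "stop_codon", "gap_after"],
               [[f.name, f.feature_class, f.start, f.end, f.length, f.strand,
                 f.anticodon, f.start_codon, f.stop_codon,
                 gap_after.get(f.name)] for f in feats])
    _write_tsv(outdir / "gaps.tsv",
               ["upstream", "downstream", "gap", "kind"],
               [[g.upstream_feature, g.downstream_feature, g.gap, g.kind]
                for g in gaps])
    summary = arch.summarize_architecture(ann)
    anchor = config.anchor or (feats[0].name if feats else None)
    order = arch.gene_order(ann, anchor) if anchor else None
    return {
        "class_counts": summary.class_counts,
        "class_bp": summary.class_bp,
        "class_percent": summary.class_percent,
        "plus_strand_genes": summary.plus_strand_genes,
        "minus_strand_genes": summary.minus_strand_genes,
        "spacer_total_bp": summary.spacer_total_bp,
        "spacer_regions": summary.spacer_regions,
        "overlap_total_bp": summary.overlap_total_bp,
        "overlap_regions": summary.overlap_regions,
        "largest_spacers": [[g.upstream_feature, g.downstream_feature, g.gap]
                            for g in summary.largest_spacers],
        "gene_order": order.to_strings() if order else [],
    }


def _stage_composition(ann: GenomeAnnotation, outdir: Path) -> dict:
    rows, raw = [], {}
    targets = [f.name for f in ann.sorted_features()
               if f.feature_class in ("PCG", "rRNA")]
    for name in targets + ["overall"]:
        if name == "overall":
            profile = comp.base_composition(ann.sequence)
            length = ann.genome_length
        else:
            profile = comp.feature_composition(ann, name, frame="sense")
            length = profile.length
        r = profile.rounded()
        rows.append([name, length, r["T%"], r["C%"], r["A%"], r["G%"],
                     r["AT%"], r["GC%"], r["GC_skew"], r["AT_skew"]])
        raw[name] = {"length": length,
                     "a": profile.a, "t": profile.t,
                     "g": profile.g, "c": profile.c,
                     "at_percent": profile.at_percent,
                     "at_skew": profile.at_skew,
                     "gc_skew": profile.gc_skew}
    _write_tsv(outdir / "composition.tsv",
               ["gene", "length", "T%", "C%", "A%", "G%", "AT%", "GC%",
                "GC_skew", "AT_skew"], rows)
    return raw


def _stage_codons(ann: GenomeAnnotation, config: RunConfig,
                  outdir: Path) -> dict:
    code = cu.GeneticCode.from_ncbi_table(config.code_id)
    starts, stops, incomplete = cu.start_stop_census(ann)
    counts = cu.codon_census(ann, code=code)
    table = cu.rscu(counts, code=code, family_mode=config.family_mode)
    _write_tsv(outdir / "codons.tsv",
               ["codon", "amino_acid", "family", "N", "RSCU"],
               [[r.codon, r.amino_acid, r.family, int(r.n), _fmt(r.rscu, 2)]
                for r in table.itertuples()])
    return {"start_codons": dict(starts), "stop_codons": dict(stops),
            "incomplete_stop_codons": dict(incomplete),
            "rscu": {r.codon: r.rscu for r in table.itertuples()}}


def _stage_trna(ann: GenomeAnnotation, outdir: Path) -> dict:
    folded = {}
    rows, raw = [], {}
    for f in ann.sorted_features():
        if f.feature_class != "tRNA" or f.anticodon is None:
            continue
        seq = ann.feature_sequence(f.name, frame="sense")
        if not 50 <= len(seq) <= 100 or f.anticodon not in seq:
            logger.info("%s: skipped (length %d or anticodon not found)",
                        f.name, len(seq))
            continue
        result = trna.fold_cloverleaf(seq, f.anticodon)
        folded[f.name] = result
        rows.append([f.name, len(seq), result.is_cloverleaf,
                     result.has_dhu, result.has_t_arm,
                     len(result.noncanonical_pairs)])
        raw[f.name] = {"cloverleaf": result.is_cloverleaf,
                       "dhu": result.has_dhu, "t_arm": result.has_t_arm,
                       "noncanonical": [[p.arm, p.index, p.pair_type]
                                        for p in result.noncanonical_pairs]}
    _write_tsv(outdir / "trna.tsv",
               ["trna", "length", "cloverleaf", "dhu_arm", "t_arm",
                "noncanonical_pairs"], rows)
    census = trna.mismatch_census(folded) if folded else None
    if census is not None:
        census.to_csv(outdir / "trna_mismatches.tsv", sep="\t", index=False)
    return raw


# ---------------------------------------------------------------------------
# comparative mode

def read_gene_orders(path: str | os.PathLike) -> list[rearr.GeneOrder]:
    """Multi-genome gene-order TSV: ``species<TAB>comma-separated labels``."""
    orders = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            species, labels = line.split("\t", 1)
            orders.append(rearr.GeneOrder.from_strings(
                species, labels.split(",")))
    return orders


def write_gene_orders(orders: list[rearr.GeneOrder],
                      path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for o in orders:
            fh.write(f"{o.label}\t{','.join(o.to_strings())}\n")


def run_compare(panel: list[rearr.GeneOrder], reference: rearr.GeneOrder,
                outdir: str) -> dict:
    """RS per genome, RF per gene, conserved blocks per genome."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rs_rows, block_rows = [], []
    per_gene_all = {}
    for order in panel:
        scores, rs = rearr.rearrangement_score(order, reference)
        per_gene_all[order.label] = scores
        rs_rows.append([order.label, rs])
        for i, block in enumerate(rearr.shared_blocks(order, reference)):
            block_rows.append([order.label, i,
                               ",".join(("+" if s > 0 else "-") + g
                                        for g, s in block)])
    rf = rearr.rearrangement_frequency(panel, reference)
    _write_tsv(out / "rs.tsv", ["species", "RS"], rs_rows)
    _write_tsv(out / "rf.tsv", ["gene", "RF_percent"],
               [[g, round_half_up(v, 2)] for g, v in sorted(rf.items())])
    _write_tsv(out / "blocks.tsv", ["species", "block", "genes"], block_rows)
    return {"rs": {label: dict(scores) for label, scores in per_gene_all.items()},
            "rs_total": dict(rs_rows), "rf": rf}
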