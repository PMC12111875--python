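"""Codon extraction, start/stop censuses, and RSCU.

Relative synonymous codon usage of codon *c* in a synonymous family *F*:

    RSCU(c) = N(c) * |F| / sum_{c' in F} N(c')

i.e. observed frequency over the family mean; 1 means no bias.  RSCU is
scale-invariant, so N may be raw counts, per-gene means or percentages.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial: AUA=Met, UGA=Trp, AGA/AGG=Ser).  Two family partitions are
offered: ``code_families`` groups codons strictly by the amino acid the
code assigns (Ser is then the 8-codon UCN+AGN family), while
``paper_compat`` mirrors the grouping conventional in published mitogenome
RSCU tables (Ser as the UCN+AGY 6-family, AGA/AGG as a separate 2-family,
UAA/UAG and UGA/UGG as 2-families).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd
from Bio.Data import CodonTable

from .annotation_io import GenomeAnnotation

__all__ = ["GeneticCode", "extract_cds", "start_stop_census", "rscu",
           "codon_census", "BASES"]

BASES = "TCAG"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def _to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass
class GeneticCode:
    """A codon->amino-acid map with its synonymous-family partition."""

    name: str
    table_id: int
    codon_to_aa: dict[str, str]          # DNA codons; '*' for stops
    start_codons: frozenset[str]
    families: dict[str, str]             # DNA codon -> family id

    @classmethod
    def from_ncbi_table(cls, table_id: int = 5) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = {c: tbl.forward_table.get(c, "*") for c in ALL_CODONS}
        families = {c: codon_to_aa[c] for c in ALL_CODONS}
        return cls(name=tbl.names[0], table_id=table_id,
                   codon_to_aa=codon_to_aa,
                   start_codons=frozenset(tbl.start_codons),
                   families=families)

    def family_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            out.setdefault(self.families[codon], []).append(codon)
        return out

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(_to_dna(codon)) == "*"


# Family partition used by conventional mitogenome RSCU tables: two-codon
# AGA/AGG and UGA/UGG families, stops as their own pair, Ser as UCN+AGY.
_PAPER_COMPAT_FAMILIES: dict[str, str] = {}
for _c4 in ("TC", "CC", "AC", "GC", "CG", "GG", "GT", "CT"):
    for _b in BASES:
        _PAPER_COMPAT_FAMILIES[_c4 + _b] = {
            "TC": "Ser", "CC": "Pro", "AC": "Thr", "GC": "Ala",
            "CG": "Arg", "GG": "Gly", "GT": "Val", "CT": "Leu"}[_c4]
_PAPER_COMPAT_FAMILIES.update({
    "TTT": "Phe", "TTC": "Phe", "TTA": "Leu", "TTG": "Leu",
    "ATT": "Ile", "ATC": "Ile", "ATA": "Met", "ATG": "Met",
    "TAT": "Tyr", "TAC": "Tyr", "TAA": "Ter", "TAG": "Ter",
    "CAT": "His", "CAC": "His", "CAA": "Gln", "CAG": "Gln",
    "AAT": "Asn", "AAC": "Asn", "AAA": "Lys", "AAG": "Lys",
    "GAT": "Asp", "GAC": "Asp", "GAA": "Glu", "GAG": "Glu",
    "TGT": "Cys", "TGC": "Cys", "TGA": "Trp*", "TGG": "Trp*",
    "AGT": "Ser", "AGC": "Ser", "AGA": "Arg2", "AGG": "Arg2",
})
assert len(_PAPER_COMPAT_FAMILIES) == 64


def extract_cds(ann: GenomeAnnotation, gene: str,
                code: Optional[GeneticCode] = None
                ) -> tuple[list[str], Optional[str]]:
    """Sense-strand codons of a protein-coding gene.

    Returns ``(codons, incomplete_stop)`` where ``incomplete_stop`` is the
    trailing 1-2 nt of a truncated stop codon (completed to TAA by mRNA
    polyadenylation), excluded from the codon list; ``None`` if the length
    is an exact codon multiple.  An in-frame internal stop under the code
    triggers a warning (possible misannotation), not an error.
    """
    feat = ann.get(gene)
    if feat.feature_class != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    seq = ann.feature_sequence(gene, frame="sense")
    rem = len(seq) % 3
    incomplete = seq[len(seq) - rem:] if rem else None
    body = seq[:len(seq) - rem] if rem else seq
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    if code is not None:
        for i, codon in enumerate(codons[:-1]):
            if code.is_stop(codon):
                warnings.warn(
                    f"{gene}: internal stop codon {codon} at codon {i + 1} "
                    "(possible misannotation)", stacklevel=2)
    return codons, incomplete


def start_stop_census(ann: GenomeAnnotation
                      ) -> tuple[Counter, Counter, Counter]:
    """Multisets of start codons, complete stops and incomplete stops.

    Uses annotated start/stop codon fields when present; falls back to the
    sequence for protein-coding features lacking them.
    """
    starts: Counter = Counter()
    stops: Counter = Counter()
    incomplete: Counter = Counter()
    for f in ann.features:
        if f.feature_class != "PCG":
            continue
        start_c, stop_c = f.start_codon, f.stop_codon
        if (start_c is None or stop_c is None) and ann.sequence is not None:
            codons, inc = extract_cds(ann, f.name)
            start_c = start_c or (codons[0] if codons else None)
            if stop_c is None:
                stop_c = inc if inc is not None else (
                    codons[-1] if codons else None)
        if start_c:
            starts[start_c] += 1
        if stop_c:
            if len(stop_c) < 3:
                incomplete[stop_c] += 1
            else:
                stops[stop_c] += 1
    return starts, stops, incomplete


def codon_census(ann: GenomeAnnotation,
                 code: Optional[GeneticCode] = None,
                 include_stops: bool = True) -> Counter:
    """Pooled codon counts over all protein-coding genes.

    Incomplete stop codons are excluded; complete stop codons are included
    unless ``include_stops`` is False.
    """
    code = code or GeneticCode.from_ncbi_table(5)
    counts: Counter = Counter()
    for f in ann.features:
        if f.feature_class != "PCG":
            continue
        codons, _ = extract_cds(ann, f.name, code=code)
        for codon in codons:
            if not include_stops and code.is_stop(codon):
                continue
            counts[codon] += 1
    return counts


def rscu(counts: Mapping[str, float], code: Optional[GeneticCode] = None,
         family_mode: str = "code_families") -> pd.DataFrame:
    """RSCU table from per-codon counts (RNA or DNA keys accepted).

    Returns one row per codon (all 64): RNA codon, amino acid, family id,
    N, family size, RSCU.  Within every family with a nonzero total,
    RSCU sums to the family size; zero-total families report RSCU 0.
    """
    code = code or GeneticCode.from_ncbi_table(5)
    if family_mode == "code_families":
        fam_of = code.families
    elif family_mode == "paper_compat":
        fam_of = _PAPER_COMPAT_FAMILIES
    else:
        raise ValueError(f"unknown family_mode {family_mode!r}")

    n = {c: 0.0 for c in ALL_CODONS}
    for codon, count in counts.items():
        dna = _to_dna(codon)
        if dna not in n:
            raise ValueError(f"not a codon: {codon!r}")
        if count < 0:
            raise ValueError(f"negative count for {codon}")
        n[dna] += float(count)

    members: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        members.setdefault(fam_of[codon], []).append(codon)

    rows = []
    for fam, codons in members.items():
        total = sum(n[c] for c in codons)
        k = len(codons)
        for c in codons:
            val = n[c] * k / total if total > 0 else 0.0
            rows.append({"codon": _to_rna(c),
                         "amino_acid": code.codon_to_aa[c],
                         "family": fam, "n": n[c],
                         "family_size": k, "rscu": val})
    df = pd.DataFrame(rows).set_index("codon")
    return df.loc[[_to_rna(c) for c in ALL_CODONS]].reset_index()
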