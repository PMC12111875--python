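"""Read, write and validate mitogenome annotations.

Coordinates are 1-based and fully inclusive on both ends, the convention of
GenBank flat files and GFF3, so ``length = end - start + 1`` with no shifting
anywhere.  A feature that runs across the origin of a circular genome is
stored with ``end > genome_length`` ("unwrapped" representation).

Three interchange formats are supported:

* a simple TSV dialect (columns ``name  class  start  end  strand
  [anticodon  start_codon  stop_codon]``, with ``#genome_length=`` /
  ``#topology=`` header pragmas),
* GFF3 (read via :mod:`gffutils`, written directly), and
* GenBank flat files (via Biopython; a sequence is required to write).

Round-tripping write -> read is the identity on every field for all three.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Feature",
    "GenomeAnnotation",
    "AnnotationParseError",
    "AnnotationValidationError",
    "CANONICAL_GENES",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

#: The 37 canonical animal mitochondrial gene labels.
CANONICAL_GENES = frozenset(
    ["cox1", "cox2", "cox3", "cytb", "atp6", "atp8",
     "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
     "rrnS", "rrnL"]
    + ["trn" + aa for aa in "ACDEFGHIKMNPQRTVWY"]
    + ["trnL1", "trnL2", "trnS1", "trnS2"]
)

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "other")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationParseError(ValueError):
    """A file could not be parsed in its declared format."""


class AnnotationValidationError(ValueError):
    """A parsed annotation violates the genome model invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_sequence(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AnnotationValidationError(
            f"sequence contains characters outside ACGTN: {sorted(bad)}")
    return seq


@dataclass
class Feature:
    """One annotated gene/RNA with 1-based inclusive circular coordinates."""

    name: str
    feature_class: str
    start: int
    end: int
    strand: str  # "+" or "-"
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationValidationError(
                f"{self.name}: unknown feature class {self.feature_class!r}")
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"{self.name}: strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise AnnotationValidationError(
                f"{self.name}: invalid span {self.start}..{self.end}")
        if self.anticodon is not None and self.feature_class != "tRNA":
            raise AnnotationValidationError(
                f"{self.name}: anticodon given for non-tRNA feature")
        if self.feature_class != "PCG" and (
                self.start_codon is not None or self.stop_codon is not None):
            raise AnnotationValidationError(
                f"{self.name}: start/stop codons given for non-PCG feature")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop(self) -> bool:
        """True if the annotated stop codon is a 1-2 nt truncation
        (completed to TAA by post-transcriptional polyadenylation)."""
        return self.stop_codon is not None and len(self.stop_codon) < 3

    @property
    def signed_label(self) -> str:
        return ("+" if self.strand == "+" else "-") + self.name


@dataclass
class GenomeAnnotation:
    """A circular (or linear) genome with its ordered feature list."""

    genome_length: int
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise AnnotationValidationError(
                f"topology must be circular or linear, got {self.topology!r}")
        if self.genome_length < 1:
            raise AnnotationValidationError("genome_length must be positive")
        if self.sequence is not None:
            self.sequence = _clean_sequence(self.sequence)
            if len(self.sequence) != self.genome_length:
                raise AnnotationValidationError(
                    f"sequence length {len(self.sequence)} != "
                    f"genome_length {self.genome_length}")
        for f in self.features:
            if f.start > self.genome_length:
                raise AnnotationValidationError(
                    f"{f.name}: start {f.start} beyond genome length")
            if f.end > self.genome_length and self.topology != "circular":
                raise AnnotationValidationError(
                    f"{f.name}: span {f.start}..{f.end} runs past the end of "
                    "a linear genome")

    def sorted_features(self) -> list[Feature]:
        """Features in start order; ties broken by longer feature first."""
        return sorted(self.features, key=lambda f: (f.start, -f.length))

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def feature_sequence(self, name: str, frame: str = "sense") -> str:
        """Nucleotide sequence of a feature.

        ``frame='sense'`` returns the coding-strand sequence (reverse
        complement of the plus-strand span for minus features);
        ``frame='genome_plus'`` returns the plus-strand span as-is.
        Wrap-around spans on circular genomes are honored.
        """
        if self.sequence is None:
            raise ValueError("annotation carries no sequence")
        if frame not in ("sense", "genome_plus"):
            raise ValueError(f"unknown frame {frame!r}")
        f = self.get(name)
        if f.end <= self.genome_length:
            span = self.sequence[f.start - 1:f.end]
        else:
            if self.topology != "circular":
                raise AnnotationValidationError(
                    f"{name}: wrap-around span on linear genome")
            span = (self.sequence[f.start - 1:] +
                    self.sequence[:f.end - self.genome_length])
        if frame == "sense" and f.strand == "-":
            span = reverse_complement(span)
        return span


# ---------------------------------------------------------------------------
# TSV dialect

_TSV_COLUMNS = ("name", "class", "start", "end", "strand",
                "anticodon", "start_codon", "stop_codon")


def _parse_tsv(text: str, path: str) -> GenomeAnnotation:
    genome_length = None
    topology = "circular"
    features: list[Feature] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("genome_length"):
                genome_length = int(body.split("=", 1)[1])
            elif body.startswith("topology"):
                topology = body.split("=", 1)[1].strip()
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if parts[0] == "name":  # column header
            continue
        if len(parts) < 5:
            raise AnnotationParseError(
                f"{path}:{lineno}: expected at least 5 columns, got {len(parts)}")
        parts += [""] * (8 - len(parts))
        name, cls, start, end, strand, anticodon, startc, stopc = parts[:8]
        if cls not in FEATURE_CLASSES:
            raise AnnotationParseError(
                f"{path}:{lineno}: unknown feature class {cls!r}")
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise AnnotationParseError(
                f"{path}:{lineno}: non-integer coordinates") from exc
        try:
            features.append(Feature(
                name=name, feature_class=cls, start=start_i, end=end_i,
                strand=strand,
                anticodon=anticodon or None,
                start_codon=startc or None,
                stop_codon=stopc or None,
            ))
        except AnnotationValidationError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
    if genome_length is None:
        if not features:
            raise AnnotationParseError(
                f"{path}: no #genome_length pragma and no features")
        genome_length = max(f.end for f in features)
    return GenomeAnnotation(genome_length=genome_length, topology=topology,
                            features=features)


def _format_tsv(ann: GenomeAnnotation) -> str:
    out = [f"#genome_length={ann.genome_length}",
           f"#topology={ann.topology}",
           "\t".join(_TSV_COLUMNS)]
    for f in ann.features:
        out.append("\t".join([
            f.name, f.feature_class, str(f.start), str(f.end), f.strand,
            f.anticodon or "", f.start_codon or "", f.stop_codon or ""]))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPE_BY_CLASS = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                      "other": "region"}
_CLASS_BY_GFF_TYPE = {v: k for k, v in _GFF_TYPE_BY_CLASS.items()}
_GFF_SEQID = "genome"


def _parse_gff3(text: str, path: str) -> GenomeAnnotation:
    import gffutils

    genome_length = None
    topology = "linear"
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                genome_length = int(parts[3])
        if line.startswith("#") and "circular" in line.lower():
            topology = "circular"
    try:
        db = gffutils.create_db(text, ":memory:", from_string=True,
                                merge_strategy="create_unique",
                                keep_order=True)
    except Exception as exc:
        raise AnnotationParseError(f"{path}: GFF3 parse failed: {exc}") from exc

    features = []
    for rec in db.all_features(order_by="start"):
        if rec.featuretype == "region" and rec.attributes.get("Is_circular"):
            topology = "circular"
            genome_length = rec.end
            continue
        cls = _CLASS_BY_GFF_TYPE.get(rec.featuretype, "other")
        attrs = rec.attributes

        def one(key: str) -> Optional[str]:
            vals = attrs.get(key)
            return vals[0] if vals else None

        end = rec.end
        wrap = one("wrap_end")
        if wrap is not None:  # wrap-around span flattened for GFF3 emission
            end = int(wrap)
        try:
            features.append(Feature(
                name=one("Name") or one("ID") or "other",
                feature_class=cls, start=rec.start, end=end,
                strand=rec.strand if rec.strand in "+-" else "+",
                anticodon=one("anticodon"),
                start_codon=one("start_codon"),
                stop_codon=one("stop_codon"),
            ))
        except AnnotationValidationError as exc:
            raise AnnotationParseError(f"{path}: {exc}") from exc
    if genome_length is None:
        raise AnnotationParseError(
            f"{path}: no ##sequence-region or circular region directive")
    features.sort(key=lambda f: (f.start, -f.length))
    return GenomeAnnotation(genome_length=genome_length, topology=topology,
                            features=features)


def _format_gff3(ann: GenomeAnnotation) -> str:
    lines = ["##gff-version 3",
             f"##sequence-region {_GFF_SEQID} 1 {ann.genome_length}"]
    circ = ";Is_circular=true" if ann.topology == "circular" else ""
    lines.append("\t".join([
        _GFF_SEQID, "mitoprofile", "region", "1", str(ann.genome_length),
        ".", "+", ".", f"ID=region0{circ}"]))
    for i, f in enumerate(ann.features):
        attrs = [f"ID=feat{i}", f"Name={f.name}"]
        end = f.end
        if f.end > ann.genome_length:  # unwrapped span: flag true end
            attrs.append(f"wrap_end={f.end}")
            end = ann.genome_length
        for key, val in (("anticodon", f.anticodon),
                         ("start_codon", f.start_codon),
                         ("stop_codon", f.stop_codon)):
            if val:
                attrs.append(f"{key}={val}")
        lines.append("\t".join([
            _GFF_SEQID, "mitoprofile", _GFF_TYPE_BY_CLASS[f.feature_class],
            str(f.start), str(end), ".", f.strand, ".", ";".join(attrs)]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GenBank flat file

_GB_TYPE_BY_CLASS = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                     "other": "misc_feature"}
_CLASS_BY_GB_TYPE = {v: k for k, v in _GB_TYPE_BY_CLASS.items()}


def _parse_genbank(path: str) -> GenomeAnnotation:
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:
        raise AnnotationParseError(f"{path}: GenBank parse failed: {exc}") from exc
    if len(records) != 1:
        raise AnnotationParseError(
            f"{path}: expected exactly one GenBank record, got {len(records)}")
    rec = records[0]
    length = len(rec.seq)
    topology = rec.annotations.get("topology", "linear")
    features = []
    for gf in rec.features:
        if gf.type == "source":
            continue
        cls = _CLASS_BY_GB_TYPE.get(gf.type, "other")
        quals = gf.qualifiers

        def one(key: str) -> Optional[str]:
            vals = quals.get(key)
            return vals[0] if vals else None

        loc = gf.location
        if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
            # origin-spanning join(a..L, 1..b) -> unwrapped a..L+b
            p1, p2 = loc.parts
            start = int(p1.start) + 1
            end = length + int(p2.end)
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
        strand = "-" if loc.strand == -1 else "+"
        try:
            features.append(Feature(
                name=one("gene") or one("product") or "other",
                feature_class=cls, start=start, end=end, strand=strand,
                anticodon=one("anticodon"),
                start_codon=one("start_codon"),
                stop_codon=one("stop_codon"),
            ))
        except AnnotationValidationError as exc:
            raise AnnotationParseError(f"{path}: {exc}") from exc
    seq = str(rec.seq)
    return GenomeAnnotation(genome_length=length, topology=topology,
                            features=features, sequence=seq)


def _format_genbank(ann: GenomeAnnotation) -> str:
    if ann.sequence is None:
        raise ValueError("GenBank output requires a sequence")
    rec = SeqRecord(Seq(ann.sequence), id="mitogenome", name="mitogenome",
                    description="mitogenome annotation")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = ann.topology
    for f in ann.features:
        strand = -1 if f.strand == "-" else 1
        if f.end <= ann.genome_length:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        else:
            parts = [SimpleLocation(f.start - 1, ann.genome_length, strand=strand),
                     SimpleLocation(0, f.end - ann.genome_length, strand=strand)]
            if strand == -1:
                parts = parts[::-1]
            loc = CompoundLocation(parts)
        quals = {"gene": [f.name]}
        for key, val in (("anticodon", f.anticodon),
                         ("start_codon", f.start_codon),
                         ("stop_codon", f.stop_codon)):
            if val:
                quals[key] = [val]
        rec.features.append(SeqFeature(
            loc, type=_GB_TYPE_BY_CLASS[f.feature_class], qualifiers=quals))
    buf = io.StringIO()
    SeqIO.write(rec, buf, "genbank")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Public entry points

def read_annotation(path: str | os.PathLike, format: str = "tsv") -> GenomeAnnotation:
    """Read a genome annotation in ``tsv``, ``gff3`` or ``genbank`` format."""
    path = os.fspath(path)
    if format == "genbank":
        ann = _parse_genbank(path)
    elif format in ("tsv", "gff3"):
        with open(path) as fh:
            text = fh.read()
        ann = _parse_tsv(text, path) if format == "tsv" else _parse_gff3(text, path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    _warn_on_odd_labels(ann.features)
    return ann


def write_annotation(ann: GenomeAnnotation, path: str | os.PathLike,
                     format: str = "tsv") -> None:
    """Write an annotation; formats as in :func:`read_annotation`."""
    path = os.fspath(path)
    if format == "tsv":
        text = _format_tsv(ann)
    elif format == "gff3":
        text = _format_gff3(ann)
    elif format == "genbank":
        text = _format_genbank(ann)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path, "w") as fh:
        fh.write(text)


def _warn_on_odd_labels(features: Iterable[Feature]) -> None:
    odd = sorted({f.name for f in features
                  if f.feature_class != "other"
                  and f.name not in CANONICAL_GENES})
    if odd:
        warnings.warn(
            f"non-canonical gene labels (excluded from rearrangement "
            f"scoring): {odd}", stacklevel=3)


def read_fasta(path: str | os.PathLike,
               expected_length: Optional[int] = None) -> str:
    """Read a single-record FASTA into an uppercase ACGTN string."""
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if len(records) == 0:
        raise AnnotationParseError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise AnnotationParseError(
            f"{path}: expected one FASTA record, found {len(records)} "
            f"(duplicate records are not allowed)")
    seq = _clean_sequence(str(records[0].seq))
    if expected_length is not None and len(seq) != expected_length:
        raise AnnotationValidationError(
            f"{path}: sequence length {len(seq)} != expected {expected_length}")
    return seq


def write_fasta(seq: str, path: str | os.PathLike,
                name: str = "mitogenome") -> None:
    rec = SeqRecord(Seq(_clean_sequence(seq)), id=name, description="")
    SeqIO.write(rec, os.fspath(path), "fasta")
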