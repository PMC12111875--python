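"""Annotation parsing, validation and format round-trips."""

import pytest

from mitoprofile.annotation_io import (
    AnnotationParseError, AnnotationValidationError, Feature,
    GenomeAnnotation, read_annotation, read_fasta, write_annotation,
    write_fasta)
from mitoprofile.simulate import simulate_genome


def test_tsv_rows_parse_to_features(tmp_path):
    p = tmp_path / "ann.tsv"
    p.write_text("#genome_length=15318\n#topology=circular\n"
                 "trnK,tRNA,1,69,-,TTT\n"
                 "nad2,PCG,392,1383,+,,ATC,TAA\n")
    ann = read_annotation(p, format="tsv")
    trnK, nad2 = ann.features
    assert (trnK.name, trnK.start, trnK.end, trnK.strand) == ("trnK", 1, 69, "-")
    assert trnK.length == 69 and trnK.anticodon == "TTT"
    assert nad2.length == 992 and nad2.start_codon == "ATC"
    assert ann.topology == "circular" and ann.genome_length == 15318


def test_empty_feature_list_is_valid():
    ann = GenomeAnnotation(genome_length=100, features=[])
    assert ann.genome_length == 100 and ann.features == []


def test_malformed_tsv_names_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("#genome_length=100\ntrnK,tRNA,one,69,-\n")
    with pytest.raises(AnnotationParseError, match="2"):
        read_annotation(p, format="tsv")


def test_feature_outside_linear_genome_rejected():
    f = Feature(name="x", feature_class="other", start=90, end=120, strand="+")
    with pytest.raises(AnnotationValidationError):
        GenomeAnnotation(genome_length=100, topology="linear", features=[f])
    # the same wrap-around span is legal on a circular genome
    ann = GenomeAnnotation(genome_length=100, topology="circular", features=[f])
    assert ann.features[0].length == 31


def test_field_constraints():
    with pytest.raises(AnnotationValidationError):
        Feature(name="nad2", feature_class="PCG", start=1, end=30,
                strand="+", anticodon="TTT")
    with pytest.raises(AnnotationValidationError):
        Feature(name="trnK", feature_class="tRNA", start=1, end=69,
                strand="-", start_codon="ATG")
    with pytest.raises(AnnotationValidationError):
        Feature(name="x", feature_class="other", start=10, end=5, strand="+")


@pytest.mark.parametrize("fmt", ["tsv", "gff3", "genbank"])
def test_round_trip_identity(tmp_path, fmt, sim0):
    ann = sim0.annotation
    p = tmp_path / f"ann.{fmt}"
    write_annotation(ann, p, format=fmt)
    back = read_annotation(p, format=fmt)
    assert back.features == ann.features
    assert back.genome_length == ann.genome_length
    assert back.topology == ann.topology
    if fmt == "genbank":
        assert back.sequence == ann.sequence


def test_gff3_coordinates_match_tsv(tmp_path, sim0):
    """The 1-based inclusive convention is preserved bit-exact across formats."""
    ann = sim0.annotation
    write_annotation(ann, tmp_path / "a.gff3", format="gff3")
    write_annotation(ann, tmp_path / "a.tsv", format="tsv")
    g = read_annotation(tmp_path / "a.gff3", format="gff3")
    t = read_annotation(tmp_path / "a.tsv", format="tsv")
    assert [(f.name, f.start, f.end) for f in g.sorted_features()] == \
           [(f.name, f.start, f.end) for f in t.sorted_features()]


def test_wrap_around_feature_round_trips(tmp_path):
    seq = "ACGT" * 50
    f = Feature(name="x", feature_class="other", start=190, end=210, strand="+")
    ann = GenomeAnnotation(genome_length=200, topology="circular",
                           features=[f], sequence=seq)
    for fmt in ("tsv", "gff3", "genbank"):
        p = tmp_path / f"w.{fmt}"
        write_annotation(ann, p, format=fmt)
        back = read_annotation(p, format=fmt)
        assert back.features[0].start == 190 and back.features[0].end == 210
    # the extracted span wraps the origin
    assert ann.feature_sequence("x") == seq[189:] + seq[:10]


def test_fasta_length_validation(tmp_path):
    write_fasta("ACGT" * 25, tmp_path / "g.fasta")
    assert len(read_fasta(tmp_path / "g.fasta", expected_length=100)) == 100
    with pytest.raises(AnnotationValidationError):
        read_fasta(tmp_path / "g.fasta", expected_length=101)


def test_duplicate_fasta_records_rejected(tmp_path):
    (tmp_path / "two.fasta").write_text(">a\nACGT\n>b\nACGT\n")
    with pytest.raises(AnnotationParseError):
        read_fasta(tmp_path / "two.fasta")


def test_u_mapped_to_t_and_bad_alphabet_rejected(tmp_path):
    (tmp_path / "u.fasta").write_text(">a\nACGU\n")
    assert read_fasta(tmp_path / "u.fasta") == "ACGT"
    with pytest.raises(AnnotationValidationError):
        GenomeAnnotation(genome_length=4, sequence="ACGX")
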