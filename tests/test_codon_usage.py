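"""CDS extraction, start/stop censuses and RSCU."""

import pytest
from hypothesis import given, settings, strategies as st

from mitoprofile._util import round_half_up
from mitoprofile.annotation_io import Feature, GenomeAnnotation, reverse_complement
from mitoprofile.codon_usage import (ALL_CODONS, GeneticCode, codon_census,
                                     extract_cds, rscu, start_stop_census)
from mitoprofile.reference import HITAMA_CODON_N

CODE5 = GeneticCode.from_ncbi_table(5)


def _pcg(seq_sense, strand="+", name="g", start=1):
    laid = seq_sense if strand == "+" else reverse_complement(seq_sense)
    feats = [Feature(name=name, feature_class="PCG", start=start,
                     end=start + len(laid) - 1, strand=strand)]
    return GenomeAnnotation(genome_length=start + len(laid) - 1 + 3,
                            features=feats,
                            sequence="A" * (start - 1) + laid + "AAA")


def test_exact_multiple_has_no_incomplete_stop():
    codons, inc = extract_cds(_pcg("ATGTAA"), "g")
    assert codons == ["ATG", "TAA"] and inc is None


def test_trailing_t_reported_as_incomplete_stop():
    body = "ATG" + "GCA" * 433 + "T"          # 1303 nt, like nad4
    codons, inc = extract_cds(_pcg(body), "g")
    assert len(codons) == 434 and inc == "T"


def test_minus_strand_gene_read_in_sense():
    codons, _ = extract_cds(_pcg("ATTGGCTAA", strand="-"), "g")
    assert codons[0] == "ATT" and codons[-1] == "TAA"


def test_internal_stop_warns():
    with pytest.warns(UserWarning, match="internal stop"):
        extract_cds(_pcg("ATGTAAGGCTAA"), "g", code=CODE5)


def test_census_from_published_annotation(hitama):
    starts, stops, incomplete = start_stop_census(hitama)
    assert dict(starts) == {"ATT": 6, "ATG": 3, "ATA": 2, "ATC": 1, "TTG": 1}
    assert dict(stops) == {"TAA": 8, "TAG": 4}
    assert dict(incomplete) == {"T": 1}


def test_census_empty_pcg_set():
    ann = GenomeAnnotation(genome_length=100, features=[])
    starts, stops, incomplete = start_stop_census(ann)
    assert not starts and not stops and not incomplete


def test_rscu_published_examples():
    table = rscu(HITAMA_CODON_N, family_mode="paper_compat").set_index("codon")
    assert round_half_up(table.loc["UUU", "rscu"], 2) == 1.59
    assert round_half_up(table.loc["UUA", "rscu"], 2) == 2.60
    # the published grouping is internally consistent as 2-codon families
    assert table.loc["UGA", "rscu"] + table.loc["UGG", "rscu"] == pytest.approx(2.0)
    assert table.loc["AGA", "rscu"] + table.loc["AGG", "rscu"] == pytest.approx(2.0)


def test_rscu_code_families_ser_is_eightfold():
    table = rscu(HITAMA_CODON_N, family_mode="code_families")
    ser = table[table.family == "S"]
    assert len(ser) == 8
    assert ser.rscu.sum() == pytest.approx(8.0)


def test_rscu_uniform_counts_give_one():
    table = rscu({c: 2.0 for c in ALL_CODONS}).set_index("codon")
    assert all(v == pytest.approx(1.0) for v in table.rscu)


def test_rscu_zero_family_reports_zero():
    counts = {"TTT": 5.0}          # every other family has zero total
    table = rscu(counts).set_index("codon")
    assert table.loc["UUA", "rscu"] == 0.0
    assert table.loc["UUU", "rscu"] == pytest.approx(2.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=100), min_size=64,
                max_size=64))
@pytest.mark.parametrize("mode", ["code_families", "paper_compat"])
def test_rscu_family_normalization(mode, values):
    """Sum of RSCU over every family equals the family size (or 0)."""
    counts = dict(zip(ALL_CODONS, values))
    table = rscu(counts, family_mode=mode)
    for fam, grp in table.groupby("family"):
        total = grp.n.sum()
        expected = len(grp) if total > 0 else 0.0
        assert grp.rscu.sum() == pytest.approx(expected)


def test_counts_invariant_to_annotated_strand():
    sense = "ATTGGCCACTAA"
    plus = codon_census(_pcg(sense, strand="+"))
    minus = codon_census(_pcg(sense, strand="-"))
    assert plus == minus


def test_rscu_rejects_bad_input():
    with pytest.raises(ValueError):
        rscu({"XYZ": 1.0})
    with pytest.raises(ValueError):
        rscu({"TTT": -1.0})
    with pytest.raises(ValueError):
        rscu({"TTT": 1.0}, family_mode="bogus")
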