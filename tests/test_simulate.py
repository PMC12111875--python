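"""Generator contracts: determinism, ground truth, parameter recovery."""

import pytest

from mitoprofile.architecture import gene_order, intergenic_gaps
from mitoprofile.codon_usage import GeneticCode, codon_census, rscu
from mitoprofile.composition import base_composition
from mitoprofile.rearrangement import GeneOrder, rearrangement_score, shared_blocks
from mitoprofile.simulate import (RearrangementEvent, SimulationConfig,
                                  ground_truth, simulate_genome)
from mitoprofile.trna_structure import fold_cloverleaf

CODE5 = GeneticCode.from_ncbi_table(5)


def test_fixed_seed_reproduces_bytes():
    a = simulate_genome(seed=42)
    b = simulate_genome(seed=42)
    assert a.annotation.sequence == b.annotation.sequence
    assert a.annotation.features == b.annotation.features
    c = simulate_genome(seed=43)
    assert c.annotation.sequence != a.annotation.sequence


def test_genome_shape_matches_template(sim0):
    ann = sim0.annotation
    counts = {}
    for f in ann.features:
        counts[f.feature_class] = counts.get(f.feature_class, 0) + 1
    assert counts == {"PCG": 13, "tRNA": 22, "rRNA": 2}
    assert 15000 <= ann.genome_length <= 17000
    assert ann.topology == "circular"


def test_planted_gaps_equal_architecture_records(sim0):
    gaps = intergenic_gaps(sim0.annotation)
    assert [(g.upstream_feature, g.downstream_feature, g.gap)
            for g in gaps] == sim0.truth.gaps


def test_overlaps_planted_with_agreeing_bases(sim0):
    ann, truth = sim0.annotation, sim0.truth
    assert len(truth.overlaps) == 6
    by_name = {f.name: f for f in ann.features}
    for up, down, k in truth.overlaps:
        assert by_name[down].start == by_name[up].end - k + 1


def test_measured_at_matches_expectation(sim0):
    prof = base_composition(sim0.annotation.sequence)
    assert prof.at_percent == pytest.approx(
        sim0.truth.expected_at_percent, abs=1.0)
    assert prof.at_skew == pytest.approx(
        sim0.truth.expected_at_skew, abs=0.02)


def test_planted_dhu_less_trna_flagged(sim0):
    ann = sim0.annotation
    assert sim0.truth.trna_defects == {"trnS1": "no_dhu"}
    flagged = []
    for f in ann.features:
        if f.feature_class != "tRNA":
            continue
        res = fold_cloverleaf(ann.feature_sequence(f.name), f.anticodon)
        assert res.is_cloverleaf
        if not res.has_dhu:
            flagged.append(f.name)
    assert flagged == ["trnS1"]


def test_transposition_event_recovered_by_scoring():
    cfg = SimulationConfig(
        seed=9, events=[RearrangementEvent("transposition", "trnD",
                                           insert_after="nad5")])
    res = simulate_genome(cfg)
    template = GeneOrder.from_strings("template", cfg.template)
    observed = gene_order(res.annotation, anchor="trnK")
    scores, rs = rearrangement_score(observed, template)
    assert rs > 0 and scores["trnD"] == 2
    assert len(shared_blocks(observed, template)) == 3


def test_inversion_event_flips_strand():
    cfg = SimulationConfig(seed=9,
                           events=[RearrangementEvent("inversion", "cox2")])
    res = simulate_genome(cfg)
    assert res.annotation.get("cox2").strand == "-"
    template = GeneOrder.from_strings("template", cfg.template)
    scores, _ = rearrangement_score(
        gene_order(res.annotation, anchor="trnK"), template)
    assert scores["cox2"] == 4


def test_rscu_recovered_from_large_codon_sample():
    """Empirical RSCU converges to the sampling table's RSCU: within 5%
    (relative) for the heavily used codons at ~10^5 sampled codons."""
    cfg = SimulationConfig(seed=13, pcg_length_scale=30.0)
    res = simulate_genome(cfg)
    counts = codon_census(res.annotation, code=CODE5, include_stops=False)
    # drop the 13 start codons; their weight is negligible at this size
    emp = rscu(counts, code=CODE5).set_index("codon")
    truth = rscu(res.truth.codon_weights, code=CODE5).set_index("codon")
    total = sum(counts.values())
    assert total >= 100_000
    checked = 0
    for codon, w in res.truth.codon_weights.items():
        if w < 0.04:
            continue
        rna = codon.replace("T", "U")
        assert emp.loc[rna, "rscu"] == pytest.approx(
            truth.loc[rna, "rscu"], rel=0.05)
        checked += 1
    assert checked >= 5


def test_ground_truth_accessor(sim0):
    truth = ground_truth(sim0)
    assert truth is sim0.truth
    assert truth.gene_order[0] == "-trnK"


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(at_fraction=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(overlap_sizes=(3,)).validate()
    with pytest.raises(ValueError):
        cfg = SimulationConfig()
        cfg.codon_weights = {"TAA": 1.0}
        cfg.validate()
    with pytest.raises(ValueError):
        RearrangementEvent("transposition", "trnD")  # no insertion point
    with pytest.raises(ValueError):
        simulate_genome(SimulationConfig(
            seed=0, events=[RearrangementEvent("inversion", "nad99")]))
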