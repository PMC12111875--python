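"""Adjacency sets, RS/RF scoring, conserved blocks — checked against an
independent brute-force oracle on small signed circular orders."""

import itertools
import random

import pytest

from mitoprofile.rearrangement import (GeneOrder, adjacency_set,
                                       rearrangement_frequency,
                                       rearrangement_score, shared_blocks)
from mitoprofile.reference import ANCESTRAL_INSECT_ORDER


def O(label, *genes):
    return GeneOrder.from_strings(label, genes)


# ---------------------------------------------------------------------------
# independent oracle: direct circular scanning, no canonicalization machinery

def _oracle_adjacent(order, pair):
    """Is the signed ordered pair adjacent on the circle (either reading)?"""
    genes = order.genes
    n = len(genes)
    (a, sa), (b, sb) = pair
    for i in range(n):
        x, y = genes[i], genes[(i + 1) % n]
        if (x, y) == ((a, sa), (b, sb)):
            return True
        if (x, y) == ((b, -sb), (a, -sa)):
            return True
    return False


def _oracle_scores(target, reference):
    shared = target.names() & reference.names()
    t = target.restrict(shared)
    r = reference.restrict(shared)
    n = len(t.genes)
    ref_signs = dict(r.genes)
    scores = {}
    for i, (g, s) in enumerate(t.genes):
        up = t.genes[(i - 1) % n]
        down = t.genes[(i + 1) % n]
        sc = 0
        if not _oracle_adjacent(r, (up, (g, s))):
            sc += 1
        if not _oracle_adjacent(r, ((g, s), down)):
            sc += 1
        if s != ref_signs[g]:
            sc += 2
        scores[g] = sc
    return scores


# ---------------------------------------------------------------------------

def test_adjacency_set_basics():
    order = O("x", "+a", "+b", "+c")
    assert len(adjacency_set(order)) == 3
    rotated = O("x", "+b", "+c", "+a")
    assert adjacency_set(rotated) == adjacency_set(order)


def test_adjacency_reflection_with_sign_flip_is_identical():
    """Exhaustive over all 3-gene signed orders: reading the circle backwards
    with flipped signs yields the same canonical adjacency set."""
    for signs in itertools.product((1, -1), repeat=3):
        genes = tuple(zip("abc", signs))
        fwd = GeneOrder("f", genes)
        rev = GeneOrder("r", tuple((g, -s) for g, s in reversed(genes)))
        assert adjacency_set(fwd) == adjacency_set(rev)


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError):
        O("x", "+a", "+a", "+b")


def test_self_score_is_zero():
    ref = O("ref", *ANCESTRAL_INSECT_ORDER)
    scores, rs = rearrangement_score(ref, ref)
    assert rs == 0 and all(v == 0 for v in scores.values())


def test_single_inversion_scores_four():
    ref = O("ref", "+a", "+b", "+c", "+d")
    tgt = O("t", "+a", "-b", "+c", "+d")
    scores, rs = rearrangement_score(tgt, ref)
    assert scores["b"] == 4          # two broken adjacencies + flip
    assert rs == 6                   # a and c each lose one adjacency


def test_transposed_gene_scores_two_and_oracle_agrees():
    ref = O("ref", "+a", "+b", "+c", "+d", "+e")
    tgt = O("t", "+a", "+c", "+d", "+b", "+e")
    scores, rs = rearrangement_score(tgt, ref)
    assert scores["b"] == 2
    assert scores == _oracle_scores(tgt, ref)
    assert len(shared_blocks(tgt, ref)) == 3


def test_scorer_matches_oracle_exhaustively_small():
    """All signed circular orders of 4 genes against a fixed reference."""
    ref = O("ref", "+a", "+b", "+c", "+d")
    for perm in itertools.permutations("abcd"):
        for signs in itertools.product((1, -1), repeat=4):
            tgt = GeneOrder("t", tuple(zip(perm, signs)))
            scores, rs = rearrangement_score(tgt, ref)
            oracle = _oracle_scores(tgt, ref)
            assert scores == oracle
            assert rs == sum(oracle.values())


def test_scorer_matches_oracle_sampled_five_genes():
    rng = random.Random(0)
    names = list("abcde")
    ref = O("ref", *("+" + n for n in names))
    for _ in range(200):
        perm = rng.sample(names, 5)
        tgt = GeneOrder("t", tuple((g, rng.choice((1, -1))) for g in perm))
        assert rearrangement_score(tgt, ref)[0] == _oracle_scores(tgt, ref)


def test_breakpoint_double_counting_identity():
    """Sum of per-gene adjacency terms equals twice the breakpoint count."""
    ref = O("ref", "+a", "+b", "+c", "+d", "+e")
    tgt = O("t", "+a", "+d", "+c", "+b", "+e")
    scores, _ = rearrangement_score(tgt, ref)
    # no orientation flips here, so per-gene scores are pure adjacency terms
    adj_terms = sum(scores.values())
    ref_adj = adjacency_set(ref)
    broken = sum(1 for a in adjacency_set(tgt) if a not in ref_adj)
    assert adj_terms == 2 * broken


def test_rs_invariant_under_joint_rotation():
    ref = O("ref", "+a", "+b", "+c", "+d", "+e")
    tgt = O("t", "+a", "-c", "+b", "+d", "+e")
    base = rearrangement_score(tgt, ref)[1]
    for k in range(1, 5):
        r2 = GeneOrder("ref", ref.genes[k:] + ref.genes[:k])
        t2 = GeneOrder("t", tgt.genes[k:] + tgt.genes[:k])
        assert rearrangement_score(t2, r2)[1] == base


def test_missing_genes_are_skipped():
    ref = O("ref", "+a", "+b", "+c", "+d")
    tgt = O("t", "+a", "+c", "+d")       # b absent: a-c adjacency intact
    scores, rs = rearrangement_score(tgt, ref)
    assert rs == 0 and "b" not in scores
    with pytest.raises(ValueError):
        rearrangement_score(O("t", "+a", "+z"), O("r", "+a", "+q"))


def test_rf_counts_panel_fractions():
    ref = O("ref", "+a", "+b", "+c", "+d", "+e")
    moved = O("m", "+a", "+c", "+d", "+b", "+e")
    rf = rearrangement_frequency([ref, moved], ref)
    assert rf["b"] == 50.0
    rf_ref_only = rearrangement_frequency([ref], ref)
    assert all(v == 0.0 for v in rf_ref_only.values())


def test_identical_orders_form_one_block():
    ref = O("ref", "+a", "+b", "+c", "+d")
    blocks = shared_blocks(ref, ref)
    assert len(blocks) == 1 and len(blocks[0]) == 4


def test_trnk_block_alteration_breaks_at_trnm():
    """The trnK-trnA-trnI-trnM block vs the trnM-trnK-trnA-trnI variant:
    the moved trnM terminates the conserved run."""
    base = O("A", "-trnK", "-trnA", "-trnI", "+trnM", "+nad2", "+cox1")
    variant = O("B", "+trnM", "-trnK", "-trnA", "-trnI", "+nad2", "+cox1")
    blocks = shared_blocks(variant, base)
    assert any([g for g, _ in b] == ["trnK", "trnA", "trnI"] for b in blocks)
    scores, _ = rearrangement_score(variant, base)
    assert scores["trnM"] > 0
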