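"""Signed circular gene orders and rearrangement scoring.

A mitogenome's gene arrangement is a signed circular permutation of the 37
standard gene labels.  Comparative scoring against a reference order (the
ancestral insect arrangement by default) follows the qMGR-style scheme:

* per-gene score = 1 for a changed upstream signed adjacency
                 + 1 for a changed downstream signed adjacency
                 + 2 if the gene's orientation is flipped vs the reference;
* the genome rearrangement score RS is the sum of per-gene scores;
* the rearrangement frequency RF of a gene over a panel is the percentage
  of genomes (containing the gene) in which its per-gene score is nonzero.

Adjacencies are canonicalized so that reading the circle backwards with all
signs flipped yields the same adjacency set, and both orders are restricted
to their shared label set before comparison, so missing genes do not break
adjacencies.  The sum of all per-gene adjacency terms is exactly twice the
breakpoint count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["GeneOrder", "adjacency_set", "rearrangement_score",
           "rearrangement_frequency", "shared_blocks"]

SignedGene = tuple[str, int]


@dataclass(frozen=True)
class GeneOrder:
    """A species label plus its signed circular gene sequence."""

    label: str
    genes: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        names = [g for g, _ in self.genes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"{self.label}: duplicate gene labels {dup}")
        if any(s not in (1, -1) for _, s in self.genes):
            raise ValueError(f"{self.label}: signs must be +1/-1")

    @classmethod
    def from_strings(cls, label: str, genes: Iterable[str]) -> "GeneOrder":
        """Build from labels like ``-trnK`` / ``+nad2`` / ``nad2``."""
        parsed = []
        for g in genes:
            g = g.strip()
            if g.startswith("-"):
                parsed.append((g[1:], -1))
            elif g.startswith("+"):
                parsed.append((g[1:], 1))
            else:
                parsed.append((g, 1))
        return cls(label=label, genes=tuple(parsed))

    def to_strings(self) -> list[str]:
        return [("+" if s > 0 else "-") + g for g, s in self.genes]

    def names(self) -> set[str]:
        return {g for g, _ in self.genes}

    def sign_of(self, name: str) -> int:
        for g, s in self.genes:
            if g == name:
                return s
        raise KeyError(name)

    def restrict(self, names: set[str]) -> "GeneOrder":
        kept = tuple((g, s) for g, s in self.genes if g in names)
        return GeneOrder(label=self.label, genes=kept)


def _canonical(adj: tuple[SignedGene, SignedGene]
               ) -> tuple[SignedGene, SignedGene]:
    """Canonical form of a signed adjacency.

    (a,sa)->(b,sb) read backwards with flipped signs is (b,-sb)->(a,-sa);
    both map to the same canonical tuple.
    """
    (a, sa), (b, sb) = adj
    mirror = ((b, -sb), (a, -sa))
    return min(adj, mirror)


def _neighbors(order: GeneOrder) -> dict[str, tuple[SignedGene, SignedGene]]:
    """For each gene: its (upstream, downstream) signed neighbors on the circle."""
    n = len(order.genes)
    out = {}
    for i, (g, _) in enumerate(order.genes):
        out[g] = (order.genes[(i - 1) % n], order.genes[(i + 1) % n])
    return out


def adjacency_set(order: GeneOrder) -> set:
    """Canonicalized signed adjacency set of a circular order (n pairs)."""
    if len(order.genes) < 2:
        raise ValueError("need at least 2 genes for adjacencies")
    n = len(order.genes)
    return {_canonical((order.genes[i], order.genes[(i + 1) % n]))
            for i in range(n)}


def rearrangement_score(target: GeneOrder, reference: GeneOrder
                        ) -> tuple[dict[str, int], int]:
    """Per-gene disruption scores and the genome RS vs a reference order.

    Genes absent from either order are skipped (both orders are first
    restricted to the shared label set).  RS(reference, reference) == 0.
    """
    shared = target.names() & reference.names()
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between orders")
    t = target.restrict(shared)
    r = reference.restrict(shared)
    ref_adj = adjacency_set(r)
    t_nbrs = _neighbors(t)
    scores: dict[str, int] = {}
    for g, s in t.genes:
        up, down = t_nbrs[g]
        score = 0
        if _canonical((up, (g, s))) not in ref_adj:
            score += 1
        if _canonical(((g, s), down)) not in ref_adj:
            score += 1
        if s != r.sign_of(g):
            score += 2
        scores[g] = score
    return scores, sum(scores.values())


def rearrangement_frequency(panel: Sequence[GeneOrder],
                            reference: GeneOrder) -> dict[str, float]:
    """RF per gene: percent of panel genomes in which the gene is rearranged.

    The denominator for each gene counts only the genomes that contain it
    (and share >= 2 genes with the reference).
    """
    if not panel:
        raise ValueError("empty panel")
    moved: dict[str, int] = {}
    present: dict[str, int] = {}
    for order in panel:
        scores, _ = rearrangement_score(order, reference)
        for g, sc in scores.items():
            present[g] = present.get(g, 0) + 1
            if sc > 0:
                moved[g] = moved.get(g, 0) + 1
    return {g: 100.0 * moved.get(g, 0) / present[g] for g in present}


def shared_blocks(target: GeneOrder, reference: GeneOrder
                  ) -> list[list[SignedGene]]:
    """Maximal runs of target genes whose signed adjacencies are preserved.

    Every shared gene lands in exactly one block; identical orders yield a
    single block containing all genes.
    """
    shared = target.names() & reference.names()
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared genes between orders")
    t = target.restrict(shared)
    r = reference.restrict(shared)
    ref_adj = adjacency_set(r)
    n = len(t.genes)
    kept = [_canonical((t.genes[i], t.genes[(i + 1) % n])) in ref_adj
            for i in range(n)]  # kept[i]: adjacency between gene i and i+1
    if all(kept):
        return [list(t.genes)]
    # start each block just after a broken adjacency
    start = next(i for i, k in enumerate(kept) if not k) + 1
    blocks: list[list[SignedGene]] = []
    block: list[SignedGene] = []
    for off in range(n):
        i = (start + off) % n
        block.append(t.genes[i])
        if not kept[i]:
            blocks.append(block)
            block = []
    if block:
        blocks.append(block)
    return blocks
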