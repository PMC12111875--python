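"""Constraint-based cloverleaf annotation of mitochondrial tRNA genes.

This is a combinatorial annotator, not a thermodynamic folder: it searches
over placements of the four cloverleaf arms under canonical geometry
constraints and keeps the placement with the most Watson-Crick pairs.
That is the right tool for the claims mitogenome papers make about tRNAs —
which arms are present (metazoan mitochondrial trnS1 typically lacks the
DHU arm) and which stem positions carry noncanonical pairs (G-T wobbles,
T-T mismatches).

Geometry searched (DNA alphabet, 5'->3'):

* acceptor stem: exactly 7 pairs, up to 2 unpaired leading nt, up to 4
  trailing nt (discriminator); at least 5 of the 7 pairs must be canonical
  or G-T wobble, otherwise the molecule is reported as "no cloverleaf";
* DHU arm: stem 3-4 pairs, loop 4-12 nt, or absent; every stem pair must
  pair (canonical or wobble, at least 2 canonical) for the arm to count;
* anticodon arm: stem 4-5 pairs around a 7 nt loop with the anticodon at
  its center; at most one unpaired stem position;
* T arm: stem 4-5 pairs, loop 4-9 nt; at most one unpaired stem position.

G-T pairs score as paired but are reported as noncanonical, alongside true
mismatches (e.g. T-T) inside accepted stems.  Ties between placements are
broken deterministically: earliest acceptor start, then maximal total
paired positions, then shortest loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

__all__ = ["StemPair", "Arm", "CloverleafAnnotation", "fold_cloverleaf",
           "mismatch_census"]

_CANONICAL = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pair_kind(x: str, y: str) -> str:
    if (x, y) in _CANONICAL:
        return "canonical"
    if (x, y) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _pair_type(x: str, y: str) -> str:
    a, b = sorted((x, y))
    return f"{a}-{b}"


@dataclass(frozen=True)
class StemPair:
    """One base pair of a stem; positions are 1-based on the tRNA."""

    arm: str
    index: int          # 1-based position within the stem, 5' side
    pos5: int
    pos3: int
    base5: str
    base3: str
    kind: str           # canonical | wobble | mismatch

    @property
    def pair_type(self) -> str:
        return _pair_type(self.base5, self.base3)


@dataclass
class Arm:
    name: str
    stem5: tuple[int, int]              # 1-based inclusive span
    stem3: tuple[int, int]
    loop: Optional[tuple[int, int]]
    pairs: list[StemPair] = field(default_factory=list)

    @property
    def canonical(self) -> int:
        return sum(1 for p in self.pairs if p.kind == "canonical")

    @property
    def paired(self) -> int:
        return sum(1 for p in self.pairs if p.kind != "mismatch")


@dataclass
class CloverleafAnnotation:
    is_cloverleaf: bool
    arms: dict[str, Arm] = field(default_factory=dict)
    anticodon_span: Optional[tuple[int, int]] = None

    @property
    def has_dhu(self) -> bool:
        return "dhu" in self.arms

    @property
    def has_t_arm(self) -> bool:
        return "t" in self.arms

    @property
    def pairing_score(self) -> int:
        """Total paired stem positions (canonical + wobble)."""
        return sum(a.paired for a in self.arms.values())

    @property
    def canonical_pairs(self) -> int:
        return sum(a.canonical for a in self.arms.values())

    @property
    def noncanonical_pairs(self) -> list[StemPair]:
        return [p for a in self.arms.values() for p in a.pairs
                if p.kind != "canonical"]


def _stem_pairs(seq: str, name: str, s5: int, s3_start: int, k: int
                ) -> list[StemPair]:
    """Pairs of a k-pair stem: 0-based 5' start s5, 3' side start s3_start.

    Pair i matches seq[s5+i] with seq[s3_start+k-1-i].
    """
    pairs = []
    for i in range(k):
        p5, p3 = s5 + i, s3_start + k - 1 - i
        x, y = seq[p5], seq[p3]
        pairs.append(StemPair(arm=name, index=i + 1, pos5=p5 + 1, pos3=p3 + 1,
                              base5=x, base3=y, kind=_pair_kind(x, y)))
    return pairs


def _count(pairs: list[StemPair]) -> tuple[int, int]:
    canonical = sum(1 for p in pairs if p.kind == "canonical")
    paired = sum(1 for p in pairs if p.kind != "mismatch")
    return canonical, paired


def _best_optional_arm(seq: str, name: str, lo: int, hi: int,
                       stem_range: tuple[int, int],
                       loop_range: tuple[int, int],
                       require_all_paired: bool) -> Optional[Arm]:
    """Best stem-loop inside [lo, hi) (0-based, exclusive end), or None."""
    best = None
    best_key = None
    for k in range(stem_range[0], stem_range[1] + 1):
        for dl in range(loop_range[0], loop_range[1] + 1):
            total = 2 * k + dl
            for s5 in range(lo, hi - total + 1):
                pairs = _stem_pairs(seq, name, s5, s5 + k + dl, k)
                canonical, paired = _count(pairs)
                if require_all_paired:
                    if paired < k or canonical < 2:
                        continue
                else:
                    if paired < k - 1 or canonical < 2:
                        continue
                key = (canonical, paired, -dl, -s5)
                if best_key is None or key > best_key:
                    best_key = key
                    best = Arm(name=name,
                               stem5=(s5 + 1, s5 + k),
                               stem3=(s5 + k + dl + 1, s5 + 2 * k + dl),
                               loop=(s5 + k + 1, s5 + k + dl),
                               pairs=pairs)
    return best


def fold_cloverleaf(seq: str, anticodon: str) -> CloverleafAnnotation:
    """Annotate a tRNA sequence with its best-scoring cloverleaf placement.

    Returns an annotation with ``is_cloverleaf=False`` when no placement
    meets the acceptor-stem minimum (>= 5 of 7 positions paired) together
    with a valid anticodon arm; that is a result, not an exception.
    """
    seq = seq.upper().replace("U", "T")
    anticodon = anticodon.upper().replace("U", "T")
    L = len(seq)
    if not 50 <= L <= 100:
        raise ValueError(f"tRNA length {L} outside the searched 50-100 nt range")
    ac_positions = [i for i in range(L - 2) if seq[i:i + 3] == anticodon]
    if not ac_positions:
        raise ValueError(f"anticodon {anticodon} does not occur in the sequence")

    best: Optional[CloverleafAnnotation] = None
    best_key = None
    for offset in range(0, 3):                      # unpaired 5' leader
        for disc in range(0, 5):                    # 3' discriminator tail
            acc3_start = L - disc - 7
            if acc3_start <= offset + 7:
                continue
            acc_pairs = _stem_pairs(seq, "acceptor", offset, acc3_start, 7)
            acc_canon, acc_paired = _count(acc_pairs)
            if acc_paired < 5:
                continue
            acceptor = Arm(name="acceptor", stem5=(offset + 1, offset + 7),
                           stem3=(acc3_start + 1, acc3_start + 7),
                           loop=None, pairs=acc_pairs)
            inner_lo, inner_hi = offset + 7, acc3_start
            for p in ac_positions:
                loop_start = p - 2
                for k in (4, 5):
                    s5 = loop_start - k
                    s3_end = loop_start + 7 + k
                    if s5 < inner_lo or s3_end > inner_hi:
                        continue
                    ac_pairs = _stem_pairs(seq, "anticodon", s5,
                                           loop_start + 7, k)
                    c, pr = _count(ac_pairs)
                    if pr < k - 1:
                        continue
                    anticodon_arm = Arm(
                        name="anticodon", stem5=(s5 + 1, s5 + k),
                        stem3=(loop_start + 8, s3_end),
                        loop=(loop_start + 1, loop_start + 7),
                        pairs=ac_pairs)
                    dhu = _best_optional_arm(
                        seq, "dhu", inner_lo, s5, (3, 4), (4, 12),
                        require_all_paired=True)
                    t_arm = _best_optional_arm(
                        seq, "t", s3_end, inner_hi, (4, 5), (4, 9),
                        require_all_paired=False)
                    arms = {"acceptor": acceptor, "anticodon": anticodon_arm}
                    if dhu is not None:
                        arms["dhu"] = dhu
                    if t_arm is not None:
                        arms["t"] = t_arm
                    cand = CloverleafAnnotation(
                        is_cloverleaf=True, arms=arms,
                        anticodon_span=(p + 1, p + 3))
                    loops = sum((a.loop[1] - a.loop[0] + 1)
                                for a in arms.values() if a.loop)
                    key = (cand.canonical_pairs, -offset,
                           cand.pairing_score, -loops)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = cand
    if best is None:
        return CloverleafAnnotation(is_cloverleaf=False)
    return best


def mismatch_census(annotations: Mapping[str, CloverleafAnnotation]
                    ) -> pd.DataFrame:
    """Table of noncanonical stem pairs across a set of folded tRNAs.

    One row per noncanonical pair: tRNA name, arm, stem position, pair type
    (e.g. ``G-T``, ``T-T``) and kind (``wobble`` vs ``mismatch``).
    """
    if not annotations:
        raise ValueError("no annotations given")
    rows = []
    for name, ann in annotations.items():
        for p in ann.noncanonical_pairs:
            rows.append({"trna": name, "arm": p.arm, "stem_position": p.index,
                         "pair_type": p.pair_type, "kind": p.kind})
    return pd.DataFrame(rows, columns=["trna", "arm", "stem_position",
                                       "pair_type", "kind"])
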