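"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), the Perna &
Kocher strand-asymmetry measures.  Both are scale-invariant, so they accept
counts, fractions or percentages.  Percentages are computed over the non-N
length; skews of a sequence and its reverse complement are exact negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._util import round_half_up
from .annotation_io import GenomeAnnotation

__all__ = ["CompositionProfile", "base_composition", "at_skew", "gc_skew",
           "feature_composition"]


def at_skew(a: float, t: float) -> Optional[float]:
    """(A - T)/(A + T); None when A + T == 0 (undefined)."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> Optional[float]:
    """(G - C)/(G + C); None when G + C == 0 (undefined)."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


@dataclass
class CompositionProfile:
    """Base counts, percentages (of non-N length) and skews of a sequence."""

    a: int
    t: int
    g: int
    c: int
    n: int = 0

    @property
    def length(self) -> int:
        return self.a + self.t + self.g + self.c + self.n

    @property
    def effective_length(self) -> int:
        return self.a + self.t + self.g + self.c

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.effective_length

    @property
    def a_percent(self) -> float:
        return self._pct(self.a)

    @property
    def t_percent(self) -> float:
        return self._pct(self.t)

    @property
    def g_percent(self) -> float:
        return self._pct(self.g)

    @property
    def c_percent(self) -> float:
        return self._pct(self.c)

    @property
    def at_percent(self) -> float:
        return self._pct(self.a + self.t)

    @property
    def gc_percent(self) -> float:
        return self._pct(self.g + self.c)

    @property
    def at_skew(self) -> Optional[float]:
        return at_skew(self.a, self.t)

    @property
    def gc_skew(self) -> Optional[float]:
        return gc_skew(self.g, self.c)

    def rounded(self) -> dict:
        """Report-style dict: percentages to 2 decimals, skews to 3."""
        sk_at, sk_gc = self.at_skew, self.gc_skew
        return {
            "A%": round_half_up(self.a_percent, 2),
            "T%": round_half_up(self.t_percent, 2),
            "G%": round_half_up(self.g_percent, 2),
            "C%": round_half_up(self.c_percent, 2),
            "AT%": round_half_up(self.at_percent, 2),
            "GC%": round_half_up(self.gc_percent, 2),
            "AT_skew": None if sk_at is None else round_half_up(sk_at, 3),
            "GC_skew": None if sk_gc is None else round_half_up(sk_gc, 3),
        }


def base_composition(seq: str) -> CompositionProfile:
    """Count bases of an ACGTN sequence; N is excluded from percentages."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    return CompositionProfile(a=seq.count("A"), t=seq.count("T"),
                              g=seq.count("G"), c=seq.count("C"),
                              n=seq.count("N"))


def feature_composition(ann: GenomeAnnotation, name: str,
                        frame: str = "sense") -> CompositionProfile:
    """Composition of one feature's span.

    ``frame='sense'`` profiles the coding strand (minus-strand features are
    reverse-complemented first); ``frame='genome_plus'`` profiles the
    plus-strand span.  Circular wrap-around is honored.
    """
    return base_composition(ann.feature_sequence(name, frame=frame))
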