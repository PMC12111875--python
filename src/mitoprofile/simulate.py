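"""Seeded synthetic mitogenome generator with recorded ground truth.

Builds a circular annotated genome gene-by-gene so that every analysis
stage in this package can be checked against known parameters without any
sequence download:

* the gene order starts from a template (default: the published
  *H. itama* arrangement) and applies configured transposition/inversion
  events;
* protein-coding genes are a start codon, body codons drawn i.i.d. from a
  configured codon-frequency table (stop codons excluded from the body),
  and a stop codon (optionally truncated to an incomplete ``T``);
* tRNAs are built as explicit cloverleaves — complementary stems with
  configurable planted defects (missing DHU arm, G-T or T-T stem pairs);
* rRNAs and spacers are i.i.d. bases at a configured A+T fraction and
  AT/GC skew;
* intergenic spacers are drawn from an empirical length distribution;
  overlaps of 1-2 bp are planted only at junctions where the adjacent
  sequences already agree on the shared bases, so both annotations remain
  valid.

All randomness flows from a single integer seed; a fixed config + seed
reproduces the genome byte-for-byte.  The ground-truth record carries the
realized gene order, every signed gap, the codon table, the expected
base-count composition (an analytic expectation, not a measurement), and
the planted tRNA structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .annotation_io import Feature, GenomeAnnotation, reverse_complement
from .codon_usage import ALL_CODONS, GeneticCode

__all__ = ["RearrangementEvent", "SimulationConfig", "GroundTruth",
           "SimulationResult", "simulate_genome", "ground_truth",
           "build_trna", "default_codon_weights"]

_SWAP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def default_template() -> list[str]:
    from .reference import hitama_annotation
    return [f.signed_label for f in hitama_annotation().sorted_features()]


def default_codon_weights() -> dict[str, float]:
    """Published *H. itama* codon frequencies, stops removed, as DNA codons."""
    from .reference import HITAMA_CODON_N
    code = GeneticCode.from_ncbi_table(5)
    out = {}
    for rna, n in HITAMA_CODON_N.items():
        dna = rna.replace("U", "T")
        if not code.is_stop(dna):
            out[dna] = n
    total = sum(out.values())
    return {c: v / total for c, v in out.items()}


def _default_gene_meta() -> dict[str, dict]:
    from .reference import hitama_annotation
    meta = {}
    for f in hitama_annotation().features:
        meta[f.name] = {"class": f.feature_class, "length": f.length,
                        "anticodon": f.anticodon,
                        "start_codon": f.start_codon,
                        "stop_codon": f.stop_codon}
    return meta


def _default_spacers() -> list[int]:
    from .reference import HITAMA_PRINTED_SPACERS
    return [g for g in HITAMA_PRINTED_SPACERS if g >= 0]


@dataclass(frozen=True)
class RearrangementEvent:
    """A single-gene transposition and/or inversion applied to the template."""

    kind: str                      # "transposition" | "inversion" | "inverted_transposition"
    gene: str
    insert_after: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("transposition", "inversion",
                             "inverted_transposition"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if "transposition" in self.kind and self.insert_after is None:
            raise ValueError(f"{self.kind} of {self.gene} needs insert_after")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate Meliponini mitogenomes."""

    seed: int = 0
    template: list[str] = field(default_factory=default_template)
    at_fraction: float = 0.754          # background (rRNA/spacer/tRNA) A+T
    at_skew: float = -0.083             # plus-strand (A-T)/(A+T)
    gc_skew: float = -0.039
    codon_weights: dict[str, float] = field(default_factory=default_codon_weights)
    spacer_lengths: list[int] = field(default_factory=_default_spacers)
    n_overlaps: int = 6
    overlap_sizes: tuple[int, ...] = (1, 1, 1, 1, 2, 2)
    incomplete_stop_genes: tuple[str, ...] = ("nad4",)
    dhu_less_trnas: tuple[str, ...] = ("trnS1",)
    #: planted stem defects: tRNA name -> list of (arm, stem index, pair type)
    trna_mismatches: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    events: list[RearrangementEvent] = field(default_factory=list)
    pcg_length_scale: float = 1.0       # scale PCG lengths (codon-heavy runs)
    gene_meta: dict[str, dict] = field(default_factory=_default_gene_meta)

    def validate(self) -> None:
        if not 0 < self.at_fraction < 1:
            raise ValueError("at_fraction must be in (0, 1)")
        for s in (self.at_skew, self.gc_skew):
            if not -1 <= s <= 1:
                raise ValueError("skews must lie in [-1, 1]")
        if any(l < 0 for l in self.spacer_lengths):
            raise ValueError("spacer lengths must be non-negative")
        if any(k not in (1, 2) for k in self.overlap_sizes):
            raise ValueError("overlap sizes must be 1 or 2 bp")
        if abs(sum(self.codon_weights.values()) - 1.0) > 1e-9:
            raise ValueError("codon weights must sum to 1")
        code = GeneticCode.from_ncbi_table(5)
        if any(code.is_stop(c) for c in self.codon_weights):
            raise ValueError("codon weights must not contain stop codons")

    def base_probs(self) -> dict[str, float]:
        at, gc = self.at_fraction, 1.0 - self.at_fraction
        return {"A": at * (1 + self.at_skew) / 2,
                "T": at * (1 - self.at_skew) / 2,
                "G": gc * (1 + self.gc_skew) / 2,
                "C": gc * (1 - self.gc_skew) / 2}


@dataclass
class GroundTruth:
    gene_order: list[str]
    events: list[RearrangementEvent]
    gaps: list[tuple[str, str, int]]
    codon_weights: dict[str, float]
    expected_base_counts: dict[str, float]
    trna_defects: dict[str, str]
    trna_arms: dict[str, dict]
    planted_mismatches: dict[str, list[tuple[str, int, str]]]
    overlaps: list[tuple[str, str, int]]
    config: SimulationConfig

    @property
    def expected_at_percent(self) -> float:
        e = self.expected_base_counts
        total = sum(e.values())
        return 100.0 * (e["A"] + e["T"]) / total

    @property
    def expected_at_skew(self) -> float:
        e = self.expected_base_counts
        return (e["A"] - e["T"]) / (e["A"] + e["T"])


@dataclass
class SimulationResult:
    annotation: GenomeAnnotation
    truth: GroundTruth


def ground_truth(result: SimulationResult) -> GroundTruth:
    """The generator's parameter record for a simulated genome."""
    return result.truth


# ---------------------------------------------------------------------------
# sequence builders

class _Expectation:
    """Accumulates the analytic expected base counts of the plus strand."""

    def __init__(self) -> None:
        self.counts = {b: 0.0 for b in "ATGC"}

    def _add(self, probs: dict[str, float], n: float, minus: bool) -> None:
        for b, p in probs.items():
            key = _SWAP[b] if minus else b
            self.counts[key] += p * n

    def add_background(self, n: int, probs: dict[str, float],
                       minus: bool = False) -> None:
        self._add(probs, n, minus)

    def add_complement_background(self, n: int, probs: dict[str, float],
                                  minus: bool = False) -> None:
        # a stem's 3' side is the complement of bases drawn from `probs`
        self._add({_SWAP[b]: p for b, p in probs.items()}, n, minus)

    def add_literal(self, seq: str, minus: bool = False) -> None:
        for ch in seq:
            key = _SWAP[ch] if minus else ch
            self.counts[key] += 1.0

    def add_codons(self, ncodons: int, weights: dict[str, float],
                   minus: bool = False) -> None:
        probs = {b: 0.0 for b in "ATGC"}
        for codon, w in weights.items():
            for ch in codon:
                probs[ch] += w / 3.0
        self._add(probs, 3 * ncodons, minus)


def _draw_bases(rng: np.random.Generator, n: int,
                probs: dict[str, float]) -> str:
    if n == 0:
        return ""
    bases = np.array(list("ATGC"))
    p = np.array([probs[b] for b in "ATGC"])
    return "".join(rng.choice(bases, size=n, p=p / p.sum()))


def build_trna(rng: np.random.Generator, anticodon: str,
               probs: dict[str, float], dhu: bool = True,
               mismatches: Optional[list[tuple[str, int, str]]] = None,
               expect: Optional[_Expectation] = None,
               minus: bool = False) -> tuple[str, dict]:
    """Construct a cloverleaf tRNA (sense strand) with known arm spans.

    Stems are built complementary base-by-base; ``mismatches`` plants
    noncanonical pairs as (arm, stem position, pair type) with pair types
    ``G-T`` or ``T-T``.  ``dhu=False`` replaces the whole DHU arm with a
    short unpaired loop (the metazoan mitochondrial trnS1 configuration);
    the remaining inter-arm window is then too small to host a stem-loop,
    so the defect is structural, not statistical.

    Returns ``(sequence, truth)`` where truth holds 1-based arm spans and
    the planted noncanonical pairs.
    """
    mismatches = mismatches or []
    parts: list[str] = []
    truth: dict = {"arms": {}, "planted": list(mismatches), "dhu": dhu}

    def stem_pair_sides(k: int) -> tuple[str, str]:
        side5 = _draw_bases(rng, k, probs)
        side3 = "".join(_SWAP[ch] for ch in reversed(side5))
        return side5, side3

    def note(n_lit: Optional[str] = None, n_bg: int = 0,
             n_comp: int = 0) -> None:
        if expect is None:
            return
        if n_lit:
            expect.add_literal(n_lit, minus)
        if n_bg:
            expect.add_background(n_bg, probs, minus)
        if n_comp:
            expect.add_complement_background(n_comp, probs, minus)

    pos = 0

    def put(s: str) -> tuple[int, int]:
        nonlocal pos
        span = (pos + 1, pos + len(s))
        parts.append(s)
        pos += len(s)
        return span

    acc5, acc3 = stem_pair_sides(7)
    d5, d3 = stem_pair_sides(4)
    ac5, ac3 = stem_pair_sides(5)
    t5, t3 = stem_pair_sides(5)

    stems = {"acceptor": [list(acc5), list(acc3)],
             "dhu": [list(d5), list(d3)],
             "anticodon": [list(ac5), list(ac3)],
             "t": [list(t5), list(t3)]}
    for arm, idx, pair in mismatches:
        b5, b3 = pair.split("-")
        k = len(stems[arm][0])
        stems[arm][0][idx - 1] = b5
        stems[arm][1][k - idx] = b3  # 3' side runs antiparallel
    acc5, acc3 = "".join(stems["acceptor"][0]), "".join(stems["acceptor"][1])
    d5, d3 = "".join(stems["dhu"][0]), "".join(stems["dhu"][1])
    ac5, ac3 = "".join(stems["anticodon"][0]), "".join(stems["anticodon"][1])
    t5, t3 = "".join(stems["t"][0]), "".join(stems["t"][1])

    truth["arms"]["acceptor"] = {"stem5": put(acc5)}
    note(n_bg=7)
    put(_draw_bases(rng, 2, probs))
    note(n_bg=2)
    if dhu:
        s5 = put(d5)
        loop = put(_draw_bases(rng, 8, probs))
        s3 = put(d3)
        truth["arms"]["dhu"] = {"stem5": s5, "loop": loop, "stem3": s3}
        note(n_bg=4 + 8, n_comp=4)
        put(_draw_bases(rng, 1, probs))
        note(n_bg=1)
    else:
        put("AAAAA")
        note(n_lit="AAAAA")
    s5 = put(ac5)
    note(n_bg=5)
    flank1 = _draw_bases(rng, 2, probs)
    flank2 = _draw_bases(rng, 2, probs)
    loop = put(flank1 + anticodon + flank2)
    note(n_bg=4, n_lit=anticodon)
    s3 = put(ac3)
    note(n_comp=5)
    truth["arms"]["anticodon"] = {"stem5": s5, "loop": loop, "stem3": s3}
    truth["anticodon_span"] = (loop[0] + 2, loop[0] + 4)
    put(_draw_bases(rng, 4, probs))
    note(n_bg=4)
    s5 = put(t5)
    tl = put(_draw_bases(rng, 7, probs))
    s3 = put(t3)
    truth["arms"]["t"] = {"stem5": s5, "loop": tl, "stem3": s3}
    note(n_bg=5 + 7, n_comp=5)
    truth["arms"]["acceptor"]["stem3"] = put(acc3)
    note(n_comp=7)
    put(_draw_bases(rng, 1, probs))
    note(n_bg=1)
    # planted mismatches perturb the analytic expectation by <0.1% of the
    # genome; the literal/complement bookkeeping above ignores them
    return "".join(parts), truth


def _build_pcg(rng: np.random.Generator, meta: dict, cfg: SimulationConfig,
               expect: _Expectation, minus: bool) -> str:
    codons = list(cfg.codon_weights)
    w = np.array([cfg.codon_weights[c] for c in codons])
    w = w / w.sum()
    length = max(9, int(round(meta["length"] * cfg.pcg_length_scale)))
    incomplete = meta.get("incomplete", False)
    n_body = (length // 3) - (1 if incomplete else 2)
    body_idx = rng.choice(len(codons), size=n_body, p=w)
    body = "".join(codons[i] for i in body_idx)
    start = meta["start_codon"] or "ATT"
    stop = "T" if incomplete else (meta["stop_codon"] or "TAA")
    expect.add_literal(start, minus)
    expect.add_codons(n_body, cfg.codon_weights, minus)
    expect.add_literal(stop, minus)
    return start + body + stop


def _apply_events(order: list[str],
                  events: list[RearrangementEvent]) -> list[str]:
    def split(tok: str) -> tuple[str, str]:
        return tok[0], tok[1:]

    out = list(order)
    for ev in events:
        names = [split(t)[1] for t in out]
        if ev.gene not in names:
            raise ValueError(f"event gene {ev.gene!r} not in template")
        i = names.index(ev.gene)
        sign, name = split(out[i])
        if ev.kind == "inversion":
            out[i] = ("-" if sign == "+" else "+") + name
            continue
        tok = out.pop(i)
        if "inverted" in ev.kind:
            s, n = split(tok)
            tok = ("-" if s == "+" else "+") + n
        names = [split(t)[1] for t in out]
        if ev.insert_after not in names:
            raise ValueError(f"insertion point {ev.insert_after!r} missing")
        out.insert(names.index(ev.insert_after) + 1, tok)
    return out


def simulate_genome(config: Optional[SimulationConfig] = None,
                    seed: Optional[int] = None) -> SimulationResult:
    """Assemble a circular annotated genome plus its ground-truth record."""
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg.seed = seed
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    probs = cfg.base_probs()
    expect = _Expectation()

    order = _apply_events(cfg.template, cfg.events)
    names = [tok[1:] for tok in order]
    signs = [tok[0] for tok in order]

    # per-gene plus-strand sequences and metadata
    laid: list[str] = []
    metas: list[dict] = []
    trna_arms: dict[str, dict] = {}
    trna_defects: dict[str, str] = {}
    for name, sign in zip(names, signs):
        meta = dict(cfg.gene_meta.get(
            name, {"class": "other", "length": 100, "anticodon": None,
                   "start_codon": None, "stop_codon": None}))
        minus = sign == "-"
        if meta["class"] == "PCG":
            meta["incomplete"] = name in cfg.incomplete_stop_genes
            sense = _build_pcg(rng, meta, cfg, expect, minus)
            if meta["incomplete"]:
                meta["stop_codon"] = "T"
        elif meta["class"] == "tRNA":
            dhu = name not in cfg.dhu_less_trnas
            if not dhu:
                trna_defects[name] = "no_dhu"
            sense, truth = build_trna(
                rng, meta["anticodon"] or "CAT", probs, dhu=dhu,
                mismatches=cfg.trna_mismatches.get(name),
                expect=expect, minus=minus)
            trna_arms[name] = truth
        else:  # rRNA / other: background bases
            sense = _draw_bases(rng, meta["length"], probs)
            expect.add_background(meta["length"], probs, minus)
        laid.append(reverse_complement(sense) if minus else sense)
        metas.append(meta)

    n = len(order)
    gaps = [int(rng.choice(cfg.spacer_lengths)) for _ in range(n)]

    # plant overlaps where the flanking sequences already agree
    overlaps: list[tuple[str, str, int]] = []
    junctions = list(rng.permutation(n - 1))  # wrap junction not overlapped
    sizes = list(cfg.overlap_sizes)[:cfg.n_overlaps]
    for k in sizes:
        for j in list(junctions):
            up, down = laid[j], laid[j + 1]
            if len(up) <= k or len(down) <= k:
                raise ValueError("overlap larger than a neighboring feature")
            if gaps[j] >= 0 and down[:k] == up[-k:]:
                gaps[j] = -k
                overlaps.append((names[j], names[j + 1], k))
                junctions.remove(j)
                break

    # spacer expectation (the wrap spacer is accounted for after layout)
    for g in gaps[:-1]:
        if g > 0:
            expect.add_background(g, probs)

    # lay out the circle
    seq_parts: list[str] = []
    features: list[Feature] = []
    pos = 0  # bases laid so far
    for i, (name, sign, meta, s) in enumerate(zip(names, signs, metas, laid)):
        if i == 0:
            start = 1
            seq_parts.append(s)
            pos += len(s)
        else:
            g = gaps[i - 1]
            if g >= 0:
                seq_parts.append(_draw_bases(rng, g, probs))
                start = pos + g + 1
                seq_parts.append(s)
                pos += g + len(s)
            else:
                k = -g
                start = pos - k + 1
                seq_parts.append(s[k:])
                pos += len(s) - k
        is_pcg = meta["class"] == "PCG"
        features.append(Feature(
            name=name, feature_class=meta["class"], start=start,
            end=start + len(s) - 1, strand=sign,
            anticodon=meta["anticodon"] if meta["class"] == "tRNA" else None,
            start_codon=meta["start_codon"] if is_pcg else None,
            stop_codon=meta["stop_codon"] if is_pcg else None))
    wrap = gaps[-1]
    seq_parts.append(_draw_bases(rng, wrap, probs))
    expect.add_background(wrap, probs)
    genome = "".join(seq_parts)

    ann = GenomeAnnotation(genome_length=len(genome), topology="circular",
                           features=features, sequence=genome)
    gap_truth = ([(names[i], names[i + 1], gaps[i]) for i in range(n - 1)]
                 + [(names[-1], names[0], gaps[-1])])
    truth = GroundTruth(
        gene_order=[s + nm for s, nm in zip(signs, names)],
        events=list(cfg.events),
        gaps=gap_truth,
        codon_weights=dict(cfg.codon_weights),
        expected_base_counts=expect.counts,
        trna_defects=trna_defects,
        trna_arms=trna_arms,
        planted_mismatches=dict(cfg.trna_mismatches),
        overlaps=overlaps,
        config=cfg,
    )
    return SimulationResult(annotation=ann, truth=truth)
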