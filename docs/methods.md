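# Methods

`mitoprofile` characterizes annotated animal mitochondrial genomes the way
comparative mitogenomics studies report them: genome architecture,
nucleotide composition and strand skews, codon usage (RSCU), tRNA
cloverleaf features, and gene-order rearrangement scores. The reference
dataset bundled with the package is the published annotation of the
stingless bee *Heterotrigona itama* (circular, 15,318 bp; 13 PCGs, 22
tRNAs, 2 rRNAs), which also parameterizes the synthetic-genome generator.

## Coordinate model and architecture statistics

Coordinates are 1-based and inclusive on both ends (`length = end − start
+ 1`), matching GenBank and GFF3; nothing is ever shifted. A feature that
crosses the origin of a circular genome is stored "unwrapped" with `end >
genome_length`. The gap between start-sorted neighbors *i*, *j* is
`start(j) − end(i) − 1`: positive values are intergenic spacers, negative
values overlaps, zero abutting genes; on a circular genome a final record
closes the circle. This definition reproduces the published *H. itama*
spacer column value-for-value (22, 8, 35, …, −1, …, 29), and it makes the
closure identity `Σ lengths + Σ signed gaps = genome_length` exact
whenever no feature wraps the origin (on the reference annotation:
14,556 + 762 = 15,318). Ties on start are broken longer-feature-first
(none occur in the reference data). Spacer ranking is strictly by gap
size with genome order breaking ties; the published table contains one
100 bp spacer and two 87 bp spacers, and the package reports what the
coordinates imply rather than arbitrating the prose that lists "100, 100,
and 87".

The signed gene order is the start-sorted feature list rotated to a
user-chosen anchor, with the sign given by coding strand. It is invariant
under rotation of the genome coordinates (tested for rotations of 1, 100
and 7,000 bp).

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C) — the Perna–Kocher
strand-asymmetry statistics. Both are scale-invariant and accept counts
or percentages. N bases are excluded from percentage denominators; a zero
denominator yields a missing value, not an exception. Per-gene
composition is computed on the sense (coding) strand, which is the
convention that makes the per-gene numbers commensurate with codon-usage
work; the genome-wide profile is computed on the plus strand. Skews of a
sequence and its reverse complement are exact negatives (property-tested).

Rounding happens only at report time: percentages to 2 decimals, skews to
3, ties away from zero. Recomputing skews from *printed* 2-decimal
percentages carries a propagated quantization uncertainty of up to about
one unit in the third decimal (|∂skew/∂G| ≈ 2C/(G+C)² times ±0.005 per
input); the acceptance tests therefore compare recomputed skews to
printed ones within 0.001. The recomputed atp8 GC skew is −0.3498, which
this package reports as −0.350.

## Codon usage and RSCU

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial: AUA = Met, UGA = Trp, AGA/AGG = Ser), taken from
Biopython's codon tables. RSCU(c) = N(c)·k / Σ_{c′∈F} N(c′) for a
synonymous family F of size k; RSCU sums to k within every family with
nonzero counts (zero-count families report 0). Because RSCU is
scale-invariant, N may be raw counts, per-gene averages or frequencies.

Two family partitions are offered. `code_families` groups codons strictly
by the table-5 amino acid (Ser becomes the 8-codon UCN+AGN family).
`paper_compat` mirrors the grouping that published mitogenome RSCU tables
use: Ser as UCN+AGY (6), AGA/AGG as their own pair, UAA/UAG as the stop
pair, and UGA/UGG as a pair. The bundled *H. itama* RSCU values are
internally consistent with exactly that grouping (UGA 1.56 + UGG 0.44 =
2.00; the six Ser codons sum to 6.02), which is why it is offered
alongside the strict code partition.

CDS extraction splits the sense-strand sequence into triplets; a trailing
1–2 nt remainder is reported as an incomplete stop codon (completed to
TAA by polyadenylation in vivo) and excluded from codon counts. Internal
in-frame stops produce a warning with the codon position — they usually
indicate a misannotation — never an error.

## Rearrangement scoring (RS/RF)

Gene arrangements are signed circular permutations. An adjacency is an
ordered signed pair of circular neighbors, canonicalized so that reading
the circle backwards with all signs flipped yields the same set. Scoring
against a reference order (default: the ancestral insect arrangement, the
one conserved in *Apis*) assigns each gene +1 for a changed upstream
adjacency, +1 for a changed downstream adjacency, and +2 if its
orientation is flipped; the genome score RS is the sum, and the
rearrangement frequency RF of a gene over a panel is the percentage of
genomes containing it in which its score is nonzero. The published tool
this scheme operationalizes prints no formula, so the constants above are
fixed by this package and validated structurally: the scorer agrees with
an independent brute-force adjacency scan exhaustively on all signed
orders of 4 genes and on sampled orders of 5; the sum of adjacency terms
equals twice the breakpoint count; RS is invariant under joint rotation.
Genes absent from either order are skipped by restricting both circles to
the shared label set, so a missing gene does not break the adjacency of
its former neighbors. Conserved blocks are the maximal runs of preserved
signed adjacencies; a single transposition yields exactly three blocks.

## tRNA cloverleaf annotation

The annotator is a constraint-based search, not a thermodynamic folder:
the claims it supports are arm presence/absence and the identity of
noncanonical stem pairs, both of which are constraint-satisfaction
questions. Geometry searched: acceptor stem of exactly 7 pairs (up to 2
unpaired leading nt, up to 4 trailing nt including the discriminator);
DHU arm with a 3–4-pair stem and 4–12 nt loop, or absent; anticodon arm
with a 4–5-pair stem around a 7 nt loop centered on the anticodon; T arm
with a 4–5-pair stem and 4–9 nt loop. A-T and G-C score as canonical; G-T
pairs as a wobble — allowed in stems but reported as noncanonical, the
way mitogenome papers count "G-T mismatches"; anything else is a
mismatch. The DNA alphabet is used throughout because the source
annotations report T-T/G-T rather than U-U/G-U. The acceptor stem is
taken as 7 pairs (the classical length; descriptions quoting "15 bp"
count both strands plus the discriminator). A molecule with no placement
achieving ≥5 paired acceptor positions and a valid anticodon arm is
reported as "no cloverleaf" — a result, not an exception.

The best placement maximizes canonical pairs, with deterministic
tie-breaks: earliest acceptor start, then most paired positions, then
shortest loops. A candidate DHU arm must pair at every stem position
(≥2 canonical) to be accepted — this keeps the false-positive rate on
non-folding regions negligible; anticodon and T stems tolerate one
unpaired position, which lets planted T-T acceptor mismatches coexist
with a confident global placement.

## Synthetic-genome generator

The generator builds a circular annotated genome gene-by-gene so that
every analysis stage has exact ground truth. Defaults are the published
*H. itama* study conditions: the 37-gene template order and per-gene
lengths, strands, anticodons and start/stop codons from the published
annotation; body codons of protein-coding genes drawn i.i.d. from the
published codon-frequency table with stop codons removed (≈3,660 codons
per genome at the default lengths); nad4 carries the incomplete "T" stop;
background regions (rRNAs, spacers, tRNA loops) drawn i.i.d. at A+T =
0.754 with AT skew −0.083 and GC skew −0.039 (the published genome-wide
values); spacer lengths resampled from the published spacer multiset
(0–100 bp); six overlaps of 1–2 bp; trnS1 built without a DHU arm.

tRNAs are built as explicit cloverleaves with complementary stems;
defects are planted structurally: a "missing DHU" replaces the whole arm
with a 5 nt unpaired loop, leaving an inter-arm window too small to host
any stem-loop, so its detection does not depend on sampling luck.
Overlaps are planted only at junctions where the downstream feature's
first k bases already equal the upstream's last k (as in the real
nad6/cytb junction, which shares one base), so neither feature's sequence
is corrupted. All randomness flows from one integer seed; a fixed config
reproduces the genome byte-for-byte.

The ground-truth record carries the realized gene order and events, every
signed gap, the codon table, the planted tRNA structures, and the
*analytic* expected base counts of the plus strand (accumulated
per-segment from the sampling distributions, not measured from the
realized sequence), from which expected AT% and AT skew follow.

What the generator does **not** emulate: within-gene codon
autocorrelation, site-specific selection, a control region/D-loop,
substitution processes along a tree, or sequencing error. Tests that pass
on these genomes show that the analytics recover known parameters from
data with the right marginal structure — not that any biological
inference about real genomes is correct.

## Verification scale and tolerances

Recovery checks run at sizes where sampling noise is far from the
tolerance: genome A+T% is compared to its expectation within 1 percentage
point per genome (≈3σ at 15 kb); RSCU recovery uses ≥10⁵ codons in the
dedicated generator test and pools ≈73,000 codons across a 20-seed panel
in the pipeline test, asserting 5% relative agreement for codons with
sampling weight ≥0.04 (expected counts ≥3,000, so 5% is ≥2.7σ);
architecture (gaps, counts, orders) is exact. The rearrangement oracle
comparison is exhaustive at 4 genes (384 signed orders) and sampled (200)
at 5.

## Known limitations

* The published tables this package bundles contain internal
  inconsistencies (e.g. two different PCG length columns summing to
  11,031 vs 11,045 bp; a stated 42.42% vs printed 41.42% T). The package
  computes from its inputs and does not repair or arbitrate them.
* Absolute codon counts (the published N column is in per-gene-average
  units) cannot be reproduced without the deposited sequence; RSCU, being
  scale-invariant, is unaffected.
* The cloverleaf annotator does not attempt to reproduce any specific
  published secondary-structure figure; without the deposited sequence,
  its claims are validated on constructed molecules.
* GenBank output requires a sequence (the writer cannot emit records with
  undefined residues); TSV and GFF3 round-trip without one.
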