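"""Published reference data for the *Heterotrigona itama* mitogenome.

The stingless bee *H. itama* (Apidae: Meliponini) has a circular 15,318 bp
mitochondrial genome (GenBank PQ759010 / PQ766639) carrying the canonical
37 animal mitochondrial genes: 13 protein-coding genes, 22 tRNAs and
2 rRNAs.  This module transcribes the published annotation (coordinates,
strands, anticodons, start/stop codons), the published per-gene nucleotide
composition percentages, and the published codon-usage frequencies, so the
analytics in this package can be exercised on real numbers without any
sequence download.  It also carries the ancestral insect gene order used as
the default reference for rearrangement scoring.
"""

from __future__ import annotations

from .annotation_io import Feature, GenomeAnnotation

HITAMA_GENOME_LENGTH = 15318

# name, class, start, end, strand, anticodon, start_codon, stop_codon
_HITAMA_ROWS = [
    ("trnK",  "tRNA", 1,     69,    "-", "TTT", None,  None),
    ("trnA",  "tRNA", 92,    156,   "-", "TGC", None,  None),
    ("trnI",  "tRNA", 165,   231,   "-", "GAT", None,  None),
    ("trnM",  "tRNA", 267,   335,   "+", "CAT", None,  None),
    ("nad2",  "PCG",  392,   1383,  "+", None,  "ATC", "TAA"),
    ("trnC",  "tRNA", 1384,  1448,  "+", "GCA", None,  None),
    ("trnW",  "tRNA", 1457,  1524,  "+", "TCA", None,  None),
    ("trnY",  "tRNA", 1524,  1611,  "-", "GTA", None,  None),
    ("cox1",  "PCG",  1681,  3240,  "+", None,  "ATT", "TAG"),
    ("trnL2", "tRNA", 3247,  3312,  "+", "TAA", None,  None),
    ("cox2",  "PCG",  3313,  3999,  "+", None,  "ATT", "TAG"),
    ("trnD",  "tRNA", 3999,  4056,  "+", "GTC", None,  None),
    ("atp8",  "PCG",  4059,  4226,  "+", None,  "ATT", "TAA"),
    ("atp6",  "PCG",  4244,  4909,  "+", None,  "TTG", "TAG"),
    ("cox3",  "PCG",  4914,  5693,  "+", None,  "ATG", "TAG"),
    ("trnE",  "tRNA", 5702,  5769,  "+", "TTC", None,  None),
    ("nad3",  "PCG",  5770,  6123,  "+", None,  "ATA", "TAA"),
    ("trnR",  "tRNA", 6124,  6185,  "-", "TCG", None,  None),
    ("trnQ",  "tRNA", 6273,  6340,  "+", "TTG", None,  None),
    ("rrnS",  "rRNA", 6342,  7102,  "+", None,  None,  None),
    ("trnV",  "tRNA", 7101,  7165,  "+", "TAC", None,  None),
    ("rrnL",  "rRNA", 7219,  8513,  "+", None,  None,  None),
    ("trnL1", "tRNA", 8512,  8579,  "+", "TAG", None,  None),
    ("trnS1", "tRNA", 8635,  8691,  "+", "TCT", None,  None),
    ("trnP",  "tRNA", 8744,  8807,  "+", "TGG", None,  None),
    ("nad4l", "PCG",  8908,  9180,  "+", None,  "ATT", "TAA"),
    ("nad4",  "PCG",  9183,  10485, "+", None,  "ATG", "T"),
    ("trnH",  "tRNA", 10486, 10551, "+", "GTG", None,  None),
    ("nad5",  "PCG",  10552, 12204, "+", None,  "ATT", "TAA"),
    ("trnF",  "tRNA", 12221, 12286, "+", "GAA", None,  None),
    ("trnN",  "tRNA", 12307, 12375, "-", "GTT", None,  None),
    ("trnT",  "tRNA", 12406, 12471, "-", "TGT", None,  None),
    ("nad6",  "PCG",  12559, 13077, "+", None,  "ATA", "TAA"),
    ("cytb",  "PCG",  13077, 14225, "+", None,  "ATG", "TAA"),
    ("trnS2", "tRNA", 14225, 14291, "+", "TGA", None,  None),
    ("nad1",  "PCG",  14292, 15218, "-", None,  "ATT", "TAA"),
    ("trnG",  "tRNA", 15222, 15289, "-", "TCC", None,  None),
]

#: Intergenic-spacer column as printed in the published annotation, one value
#: per feature in genome order (gap to the following feature; negative =
#: overlap, the last entry wraps around the circle).
HITAMA_PRINTED_SPACERS = [
    22, 8, 35, 56, 0, 8, -1, 69, 6, 0, -1, 2, 17, 4, 8, 0, 0, 87, 1, -2,
    53, -2, 55, 52, 100, 2, 0, 0, 16, 20, 30, 87, -1, -1, 0, 3, 29,
]


def hitama_annotation() -> GenomeAnnotation:
    """The published *H. itama* annotation as a :class:`GenomeAnnotation`."""
    feats = [
        Feature(name=n, feature_class=c, start=s, end=e, strand=st,
                anticodon=ac, start_codon=sc, stop_codon=pc)
        for n, c, s, e, st, ac, sc, pc in _HITAMA_ROWS
    ]
    return GenomeAnnotation(genome_length=HITAMA_GENOME_LENGTH,
                            topology="circular", features=feats)


#: Published per-gene nucleotide composition (percent of gene length) and
#: skews for the 13 PCGs, 2 rRNAs and the whole molecule:
#: gene -> (length, T%, C%, A%, G%, AT%, GC%, GC skew, AT skew).
HITAMA_COMPOSITION = {
    "nad2":  (996,  40.70, 15.90, 31.20, 12.20, 71.90, 28.10, -0.131, -0.132),
    "cox1":  (1575, 39.34, 18.16, 27.92, 14.58, 67.26, 32.74, -0.109, -0.169),
    "cox2":  (676,  37.66, 17.70, 30.94, 13.70, 68.60, 31.40, -0.127, -0.098),
    "atp8":  (168,  39.78, 15.86, 36.72, 7.64,  76.50, 23.50, -0.349, -0.040),
    "atp6":  (666,  39.76, 21.12, 25.76, 13.36, 65.52, 34.48, -0.225, -0.214),
    "cox3":  (780,  36.68, 19.76, 30.38, 13.18, 67.06, 32.94, -0.199, -0.093),
    "nad3":  (354,  39.40, 21.20, 25.82, 13.58, 65.22, 34.78, -0.219, -0.208),
    "nad4l": (300,  48.40, 5.70,  36.04, 9.86,  84.44, 15.56, 0.267,  -0.146),
    "nad4":  (1303, 46.16, 8.16,  36.38, 9.30,  82.54, 17.46, 0.065,  -0.118),
    "nad5":  (1653, 44.56, 7.64,  39.86, 7.94,  84.42, 15.58, 0.019,  -0.056),
    "nad6":  (501,  46.50, 8.60,  38.74, 6.16,  85.24, 14.76, -0.165, -0.091),
    "cytb":  (1149, 45.00, 12.82, 32.62, 9.56,  77.62, 22.38, -0.146, -0.159),
    "nad1":  (924,  45.68, 8.44,  35.86, 10.02, 81.54, 18.46, 0.086,  -0.120),
    "rrnS":  (761,  35.26, 8.98,  40.56, 15.20, 75.82, 24.18, 0.257,  0.070),
    "rrnL":  (1316, 38.20, 9.58,  39.32, 12.90, 77.52, 22.48, 0.148,  0.014),
    "overall": (15318, 41.42, 12.22, 35.06, 11.30, 75.413, 24.587, -0.039, -0.083),
}

HITAMA_PCG_NAMES = [
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad4l", "nad4", "nad5", "nad6", "cytb", "nad1",
]

#: Published codon-usage frequencies (N, per-gene average units) for the 13
#: PCGs, RNA codon -> N.  The published table reports these alongside RSCU.
HITAMA_CODON_N = {
    "UUU": 9.7,  "UUC": 2.5,  "UUA": 6.8,  "UUG": 1.9,
    "CUU": 3.2,  "CUC": 0.7,  "CUA": 2.2,  "CUG": 0.9,
    "AUU": 11.4, "AUC": 2.3,  "AUA": 10.2, "AUG": 2.2,
    "GUU": 2.5,  "GUC": 0.6,  "GUA": 2.6,  "GUG": 0.6,
    "UCU": 2.9,  "UCC": 0.7,  "UCA": 3.6,  "UCG": 0.4,
    "CCU": 1.5,  "CCC": 0.3,  "CCA": 1.1,  "CCG": 0.2,
    "ACU": 2.3,  "ACC": 0.4,  "ACA": 1.5,  "ACG": 0.1,
    "GCU": 0.8,  "GCC": 0.3,  "GCA": 0.8,  "GCG": 0.1,
    "UAU": 5.6,  "UAC": 2.0,  "UAA": 2.1,  "UAG": 0.6,
    "CAU": 1.2,  "CAC": 0.7,  "CAA": 0.8,  "CAG": 0.5,
    "AAU": 6.1,  "AAC": 2.3,  "AAA": 5.3,  "AAG": 1.8,
    "GAU": 1.7,  "GAC": 0.5,  "GAA": 2.1,  "GAG": 0.7,
    "UGU": 0.9,  "UGC": 0.3,  "UGA": 2.1,  "UGG": 0.6,
    "CGU": 0.3,  "CGC": 0.1,  "CGA": 0.8,  "CGG": 0.1,
    "AGU": 1.3,  "AGC": 0.4,  "AGA": 2.3,  "AGG": 0.8,
    "GGU": 0.6,  "GGC": 0.2,  "GGA": 2.4,  "GGG": 0.4,
}

#: Ancestral insect (pancrustacean) mitochondrial gene order, anchored at
#: trnI, signed by coding strand.  This is the arrangement conserved in
#: *Apis* and most insects and is the default reference for RS/RF scoring.
ANCESTRAL_INSECT_ORDER = [
    "+trnI", "-trnQ", "+trnM", "+nad2", "+trnW", "-trnC", "-trnY",
    "+cox1", "+trnL2", "+cox2", "+trnK", "+trnD", "+atp8", "+atp6",
    "+cox3", "+trnG", "+nad3", "+trnA", "+trnR", "+trnN", "+trnS1",
    "+trnE", "-trnF", "-nad5", "-trnH", "-nad4", "-nad4l", "+trnT",
    "-trnP", "+nad6", "+cytb", "+trnS2", "-nad1", "-trnL1", "-rrnL",
    "-trnV", "-rrnS",
]
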