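"""Deterministic zyg-1-like fixture transcript and surrounding genome.

The screen this package analyses targets the *C. elegans* gene *zyg-1* on
chromosome II. The real WS265 reference is not shipped; instead this module
reconstructs a transcript whose genomic<->cDNA coordinate mapping reproduces,
exactly, every published coordinate pair for the intragenic suppressor set:

* g − c = 5,649,909 for c in {937, 938}
* g − c = 5,649,992 for c in {947 .. 1262}
* g − c = 5,652,014 for c in {1325 (the primary lesion), 1597}
* c.1 sits at g = 5,649,774, so g(c.−4) = 5,649,770 and g(c.−18) = 5,649,756

Those offsets force three introns (136 nt upstream of c.937, 83 nt between
c.938 and c.947, and 2,022 nt between c.1262 and c.1325); their exact
placement inside the unconstrained gaps is this module's choice. Reference
codons are fixed so that each catalogued base change forces the catalogued
amino-acid change (e.g. codon 385 = GCT so c.1154C>T gives A385V), and the
primary lesion C>T at II:5,653,339 (c.1325, codon 442) gives P442L.

Everything else (UTR filler, intron interiors, flanking sequence, the
unconstrained codons) is drawn from a fixed-seed generator, so the fixture
is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Genome, PrimaryAllele, TranscriptModel

CHROMOSOME = "II"
CHROMOSOME_LENGTH = 5_656_000

GENE_ID = "zyg-1"
TRANSCRIPT_ID = "zyg-1.t1"

# cDNA geometry
UTR5_LENGTH = 40
CODING_LENGTH = 1602          # 533 amino acids + stop
UTR3_LENGTH = 60
CDS_START_G = 5_649_774       # genomic position of c.1

# block offsets g - c, keyed by the last coding position of each exon block
_BLOCKS = (
    (600, 5_649_773),     # exon 1 coding part: c.1..600
    (939, 5_649_909),     # exon 2: c.601..939
    (1262, 5_649_992),    # exon 3: c.940..1262
    (CODING_LENGTH, 5_652_014),  # exon 4: c.1263..1602
)

EXONS = (
    (CDS_START_G - UTR5_LENGTH, 600 + 5_649_773),       # 5,649,734..5,650,373
    (601 + 5_649_909, 939 + 5_649_909),                 # 5,650,510..5,650,848
    (940 + 5_649_992, 1262 + 5_649_992),                # 5,650,932..5,651,254
    (1263 + 5_652_014, CODING_LENGTH + 5_652_014 + UTR3_LENGTH),  # 5,653,277..5,653,676
)

# codons whose reference identity is pinned by the catalogued variant effects
CONSTRAINED_CODONS = {
    1: "ATG",     # start
    313: "GAC",   # Asp: c.937G>A -> D313N, c.938A>C -> D313A
    316: "CCC",   # Pro: c.947C>A -> P316H
    319: "TCC",   # Ser: c.955T>G -> S319A, c.956C>T -> S319F
    361: "GAA",   # Glu: c.1081G>A -> E361K
    385: "GCT",   # Ala: c.1154C>T -> A385V
    409: "CAT",   # His: c.1227T>C -> H409= (synonymous)
    420: "AAT",   # Asn: c.1260T>A -> N420K
    421: "GGA",   # Gly: c.1262G>A -> G421E
    442: "CCA",   # Pro: c.1325C>T -> P442L (the primary lesion site)
    533: "AAA",   # Lys: c.1597A>G -> K533E
    534: "TAA",   # stop
}

# every genomic<->cDNA pair the fixture is constructed to satisfy
COORDINATE_PAIRS = (
    (5_650_846, 937),
    (5_650_847, 938),
    (5_650_939, 947),
    (5_650_947, 955),
    (5_650_948, 956),
    (5_651_073, 1081),
    (5_651_146, 1154),
    (5_651_219, 1227),
    (5_651_252, 1260),
    (5_651_254, 1262),
    (5_653_339, 1325),
    (5_653_611, 1597),
    (5_649_770, -4),
    (5_649_756, -18),
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

_FIXTURE_SEED = 20_211_113


@dataclass(frozen=True)
class FixtureVariant:
    """One designed intragenic substitution with its expected annotation."""

    strain_id: str
    mutagen: str
    n_filtered: int
    position: int
    ref_base: str
    alt_base: str
    c_hgvs: str
    p_hgvs: str  # empty for UTR variants


#: The designed suppressor-variant catalogue on the fixture transcript:
#: sixteen substitutions across fourteen strains, with the recurrence
#: structure of the screen (one variant seen in three strains, one in two,
#: two complex-allele pairs, two 5'UTR hits).
VARIANT_TABLE = (
    FixtureVariant("S01", "EMS", 122, 5_651_146, "C", "T", "c.1154C>T", "p.A385V"),
    FixtureVariant("S02", "ENU", 65, 5_650_939, "C", "A", "c.947C>A", "p.P316H"),
    FixtureVariant("S02", "ENU", 65, 5_650_947, "T", "G", "c.955T>G", "p.S319A"),
    FixtureVariant("S03", "EMS+ENU", 188, 5_651_254, "G", "A", "c.1262G>A", "p.G421E"),
    FixtureVariant("S04", "EMS+ENU", 176, 5_651_146, "C", "T", "c.1154C>T", "p.A385V"),
    FixtureVariant("S05", "EMS+ENU", 174, 5_649_756, "G", "A", "c.-18G>A", ""),
    FixtureVariant("S06", "ENU", 73, 5_651_219, "T", "C", "c.1227T>C", "p.H409="),
    FixtureVariant("S06", "ENU", 73, 5_651_252, "T", "A", "c.1260T>A", "p.N420K"),
    FixtureVariant("S07", "ENU", 84, 5_653_611, "A", "G", "c.1597A>G", "p.K533E"),
    FixtureVariant("S08", "ENU", 78, 5_650_847, "A", "C", "c.938A>C", "p.D313A"),
    FixtureVariant("S09", "ENU", 70, 5_651_254, "G", "A", "c.1262G>A", "p.G421E"),
    FixtureVariant("S11", "EMS+ENU", 47, 5_649_770, "T", "A", "c.-4T>A", ""),
    FixtureVariant("S12", "EMS+ENU", 126, 5_651_146, "C", "T", "c.1154C>T", "p.A385V"),
    FixtureVariant("S13", "EMS+ENU", 123, 5_651_073, "G", "A", "c.1081G>A", "p.E361K"),
    FixtureVariant("S14", "EMS+ENU", 116, 5_650_948, "C", "T", "c.956C>T", "p.S319F"),
    FixtureVariant("S15", "EMS+ENU", 111, 5_650_846, "G", "A", "c.937G>A", "p.D313N"),
)

#: The revertant strain of the catalogue: the primary site back at wildtype,
#: with a full mutagen background of 70 filtered variants.
REVERTANT_STRAIN = ("S10", "EMS+ENU", 70)


def coding_to_genomic_offset(coding_position: int) -> int:
    """The fixture's g − c offset for a coding position (1..1602)."""
    for last_c, offset in _BLOCKS:
        if coding_position <= last_c:
            return offset
    raise ValueError(f"coding position {coding_position} beyond CDS")


def fixture_primary_allele() -> PrimaryAllele:
    """The temperature-sensitive primary lesion the screen suppresses."""
    return PrimaryAllele(
        gene_id=GENE_ID,
        chromosome=CHROMOSOME,
        position=5_653_339,
        wildtype_base="C",
        mutant_base="T",
        protein_change="P442L",
    )


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lookup[rng.integers(0, 4, size=n)]


def build_fixture_transcript() -> tuple[TranscriptModel, Genome]:
    """Construct the fixture transcript and its chromosome.

    Fully deterministic: the unconstrained sequence is drawn from a fixed
    internal seed, then every constrained base (CDS codons, the two pinned
    UTR bases, GT..AG intron dinucleotides) is written on top.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    buf = bytearray(_random_bases(rng, CHROMOSOME_LENGTH).tobytes())

    # CDS: random sense codons with the constrained ones pinned
    codon_idx = rng.integers(0, len(_SENSE_CODONS), size=CODING_LENGTH // 3)
    codons = [_SENSE_CODONS[i] for i in codon_idx]
    for index, codon in CONSTRAINED_CODONS.items():
        codons[index - 1] = codon
    cds = "".join(codons)
    for c in range(1, CODING_LENGTH + 1):
        g = c + coding_to_genomic_offset(c)
        buf[g - 1] = ord(cds[c - 1])

    # pinned 5'UTR bases: c.-4 = T, c.-18 = G
    buf[(CDS_START_G - 4) - 1] = ord("T")
    buf[(CDS_START_G - 18) - 1] = ord("G")

    # canonical GT..AG dinucleotides at each intron boundary
    for (_, exon_end), (next_start, _) in zip(EXONS, EXONS[1:]):
        buf[exon_end] = ord("G")
        buf[exon_end + 1] = ord("T")
        buf[next_start - 3] = ord("A")
        buf[next_start - 2] = ord("G")

    genome = Genome({CHROMOSOME: buf.decode("ascii")})
    transcript = TranscriptModel(
        gene_id=GENE_ID,
        transcript_id=TRANSCRIPT_ID,
        chromosome=CHROMOSOME,
        strand="+",
        exons=EXONS,
        cds_start_g=CDS_START_G,
        cds_end_g=CODING_LENGTH + 5_652_014,
    )
    return transcript, genome
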