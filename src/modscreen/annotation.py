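"""Coding-effect annotation with simplified HGVS c./p. nomenclature.

Maps genomic substitutions onto transcript coordinates, edits the affected
codon under the standard genetic code (strand-aware), and renders the
compact one-letter style used in screen reports: ``c.1154C>T`` / ``p.A385V``,
``p.H409=`` for synonymous, ``c.-4T>A`` for 5'UTR, ``c.938+3A>G`` for
intronic positions anchored to the nearest coding base. 3'UTR ``c.*N``
numbering is not supported; such variants fall back to ``g.`` notation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .errors import DataIntegrityError, DomainError
from .filtering import RegionClass, classify_region
from .io import COMPLEMENT, Genome, TranscriptModel, VariantCall

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


class CdnaKind(str, Enum):
    CODING = "CODING"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRONIC = "INTRONIC"


class EffectClass(str, Enum):
    MISSENSE = "MISSENSE"
    SYNONYMOUS = "SYNONYMOUS"
    NONSENSE = "NONSENSE"
    STOP_LOSS = "STOP_LOSS"
    START_LOSS = "START_LOSS"
    SPLICE_PROX = "SPLICE_PROX"
    UTR5_VARIANT = "UTR5_VARIANT"
    UTR3_VARIANT = "UTR3_VARIANT"
    INTRONIC = "INTRONIC"


@dataclass(frozen=True)
class CdnaCoordinate:
    """A genomic position expressed in transcript (cDNA) coordinates.

    ``coding_position`` is >= 1 inside the CDS and negative (no zero,
    counting back from -1) in the 5'UTR. Intronic positions carry an
    ``intron_anchor`` = (nearest cDNA position, signed offset), positive
    downstream of the anchor in transcript orientation.
    """

    kind: CdnaKind
    coding_position: Optional[int] = None
    intron_anchor: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantCall
    gene_id: str
    transcript_id: str
    region: RegionClass
    cdna: CdnaCoordinate
    codon_index: Optional[int]
    codon_offset: Optional[int]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    effect_class: EffectClass
    c_hgvs: str
    p_hgvs: str

    @property
    def protein_token(self) -> str:
        """Report token: 'A385V' / 'H409=' for coding, 'c.-4T>A' otherwise."""
        if self.p_hgvs:
            return self.p_hgvs[2:]
        return self.c_hgvs


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _transcript_index(tr: TranscriptModel):
    """(spliced genomic positions in transcript order, position->index map,
    CDS start/end indices)."""
    spliced = tr.spliced_positions()
    index = {int(g): i for i, g in enumerate(spliced)}
    return spliced, index, index[tr.cds_start_g], index[tr.cds_end_g]


def _c_of_index(i: int, cds_i: int) -> int:
    """cDNA numbering of spliced index i: negative in the 5'UTR, no zero."""
    return i - cds_i + 1 if i >= cds_i else i - cds_i


def genomic_to_cdna(tr: TranscriptModel, position: int) -> CdnaCoordinate:
    """Map a genomic position on the transcript span to cDNA coordinates."""
    lo, hi = tr.span
    if not lo <= position <= hi:
        raise DomainError(
            f"{tr.transcript_id}: position {position} off the transcript span {lo}-{hi}"
        )
    spliced, index, cds_i, cds_end_i = _transcript_index(tr)
    if position in index:
        i = index[position]
        if i < cds_i:
            return CdnaCoordinate(kind=CdnaKind.UTR5, coding_position=_c_of_index(i, cds_i))
        if i > cds_end_i:
            return CdnaCoordinate(kind=CdnaKind.UTR3)
        return CdnaCoordinate(kind=CdnaKind.CODING, coding_position=i - cds_i + 1)

    # intronic: find the flanking exons genomically, then orient by strand
    left_end = max(e for _, e in tr.exons if e < position)
    right_start = min(s for s, _ in tr.exons if s > position)
    d_left = position - left_end
    d_right = right_start - position
    if tr.strand == "+":
        upstream_g, downstream_g = left_end, right_start
        d_up, d_down = d_left, d_right
    else:
        upstream_g, downstream_g = right_start, left_end
        d_up, d_down = d_right, d_left
    if d_up <= d_down:  # ties anchor to the donor (upstream) side
        anchor_c = _c_of_index(index[upstream_g], cds_i)
        offset = d_up
    else:
        anchor_c = _c_of_index(index[downstream_g], cds_i)
        offset = -d_down
    return CdnaCoordinate(kind=CdnaKind.INTRONIC, intron_anchor=(anchor_c, offset))


def cdna_to_genomic(tr: TranscriptModel, coding_position: int) -> int:
    """Inverse of :func:`genomic_to_cdna` for exonic positions.

    Accepts positive CDS positions and negative 5'UTR positions.
    """
    if coding_position == 0:
        raise DomainError("cDNA position 0 does not exist")
    spliced, _, cds_i, cds_end_i = _transcript_index(tr)
    i = cds_i + coding_position - 1 if coding_position > 0 else cds_i + coding_position
    if not 0 <= i < len(spliced):
        raise DomainError(f"{tr.transcript_id}: cDNA position {coding_position} off transcript")
    return int(spliced[i])


def codon_arithmetic(coding_position: int) -> tuple[int, int]:
    """Codon index (ceil(c/3)) and in-codon offset (1..3) of a CDS position."""
    if coding_position < 1:
        raise DomainError(f"coding position must be >= 1, got {coding_position}")
    codon_index = -(-coding_position // 3)
    codon_offset = coding_position - 3 * (codon_index - 1)
    return codon_index, codon_offset


def coding_sequence(tr: TranscriptModel, genome: Genome) -> str:
    """Spliced CDS in transcript orientation (reverse-complemented for '-')."""
    cds_lo, cds_hi = tr.cds_span
    parts = []
    for s, e in tr.exons:
        cs, ce = max(s, cds_lo), min(e, cds_hi)
        if cs <= ce:
            parts.append(genome.slice(tr.chromosome, cs, ce))
    seq = "".join(parts)
    if tr.strand == "-":
        seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    return seq


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _cdna_strand_base(base: str, strand: str) -> str:
    return base if strand == "+" else COMPLEMENT[base]


def annotate(
    tr: TranscriptModel,
    genome: Genome,
    variant: VariantCall,
    splice_window_nt: int = 10,
) -> EffectAnnotation:
    """Annotate one substitution against one transcript.

    The variant's REF is checked against the genome; a mismatch is a
    data-integrity error (wrong reference build or corrupted calls).
    """
    if variant.chromosome != tr.chromosome:
        raise DomainError(
            f"variant on {variant.chromosome} vs transcript on {tr.chromosome}"
        )
    genome_base = genome.base(variant.chromosome, variant.position)
    if genome_base != variant.ref_base:
        raise DataIntegrityError(
            f"strain {variant.strain_id!r} at {variant.chromosome}:{variant.position}: "
            f"REF {variant.ref_base} does not match the reference base {genome_base}"
        )

    region = classify_region([tr], variant.chromosome, variant.position, splice_window_nt)
    coord = genomic_to_cdna(tr, variant.position)
    ref_c = _cdna_strand_base(variant.ref_base, tr.strand)
    alt_c = _cdna_strand_base(variant.alt_base, tr.strand)

    codon_index = codon_offset = None
    ref_aa = alt_aa = None

    if coord.kind is CdnaKind.CODING:
        cpos = coord.coding_position
        codon_index, codon_offset = codon_arithmetic(cpos)
        cds = coding_sequence(tr, genome)
        codon = cds[3 * (codon_index - 1) : 3 * codon_index]
        if codon[codon_offset - 1] != ref_c:
            raise DataIntegrityError(
                f"{tr.transcript_id}: CDS/genome inconsistency at c.{cpos}"
            )
        mutated = codon[: codon_offset - 1] + alt_c + codon[codon_offset:]
        ref_aa = translate_codon(codon)
        alt_aa = translate_codon(mutated)
        c_hgvs = f"c.{cpos}{ref_c}>{alt_c}"
        if codon_index == 1 and ref_aa == "M" and alt_aa != "M":
            effect = EffectClass.START_LOSS
            p_hgvs = f"p.{ref_aa}{codon_index}{alt_aa}"
        elif ref_aa == alt_aa:
            effect = EffectClass.SYNONYMOUS
            p_hgvs = f"p.{ref_aa}{codon_index}="
        elif alt_aa == "*":
            effect = EffectClass.NONSENSE
            p_hgvs = f"p.{ref_aa}{codon_index}*"
        elif ref_aa == "*":
            effect = EffectClass.STOP_LOSS
            p_hgvs = f"p.*{codon_index}{alt_aa}"
        else:
            effect = EffectClass.MISSENSE
            p_hgvs = f"p.{ref_aa}{codon_index}{alt_aa}"
    elif coord.kind is CdnaKind.UTR5:
        c_hgvs = f"c.{coord.coding_position}{ref_c}>{alt_c}"
        effect = EffectClass.UTR5_VARIANT
        p_hgvs = ""
    elif coord.kind is CdnaKind.UTR3:
        c_hgvs = f"g.{variant.position}{variant.ref_base}>{variant.alt_base}"
        effect = EffectClass.UTR3_VARIANT
        p_hgvs = ""
    else:  # intronic
        anchor, offset = coord.intron_anchor
        sign = "+" if offset > 0 else ""
        c_hgvs = f"c.{anchor}{sign}{offset}{ref_c}>{alt_c}"
        effect = (
            EffectClass.SPLICE_PROX
            if region is RegionClass.SPLICE_PROX
            else EffectClass.INTRONIC
        )
        p_hgvs = ""

    return EffectAnnotation(
        variant=variant,
        gene_id=tr.gene_id,
        transcript_id=tr.transcript_id,
        region=region,
        cdna=coord,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
        c_hgvs=c_hgvs,
        p_hgvs=p_hgvs,
    )


# ---------------------------------------------------------------------------
# Complex alleles and burden summaries
# ---------------------------------------------------------------------------


def _token_sort_key(ann: EffectAnnotation) -> tuple[int, int]:
    if ann.codon_index is not None:
        return (ann.codon_index, 0)
    if ann.cdna.coding_position is not None:  # 5'UTR, negative
        return (ann.cdna.coding_position, 0)
    return (-(10**9), ann.variant.position)


def group_complex_alleles(annotations: Sequence[EffectAnnotation]) -> dict[str, str]:
    """Per-gene allele label for one strain's in-gene annotations.

    Two or more variants in the same gene join into a complex-allele label of
    protein-change tokens sorted by codon index and separated by ';', e.g.
    ``P316H;S319A``.
    """
    by_gene: dict[str, list[EffectAnnotation]] = {}
    for ann in annotations:
        by_gene.setdefault(ann.gene_id, []).append(ann)
    return {
        gene: ";".join(a.protein_token for a in sorted(group, key=_token_sort_key))
        for gene, group in by_gene.items()
    }


def round_percentage(count: int, total: int) -> Optional[float]:
    """100*count/total rounded half-up to 2 decimals; None when total is 0."""
    if total == 0:
        return None
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BurdenSummary:
    """Nonsense/splice burden of a filtered call set (percentages of total)."""

    n_total: int
    n_nonsense: int
    n_splice: int
    pct_nonsense: Optional[float]
    pct_splice: Optional[float]


def burden_from_counts(n_total: int, n_nonsense: int, n_splice: int) -> BurdenSummary:
    return BurdenSummary(
        n_total=n_total,
        n_nonsense=n_nonsense,
        n_splice=n_splice,
        pct_nonsense=round_percentage(n_nonsense, n_total),
        pct_splice=round_percentage(n_splice, n_total),
    )


def burden_summary(annotations: Sequence[EffectAnnotation]) -> BurdenSummary:
    """Count nonsense and splice-proximal annotations and their percentages."""
    n_total = len(annotations)
    n_nonsense = sum(1 for a in annotations if a.effect_class is EffectClass.NONSENSE)
    n_splice = sum(1 for a in annotations if a.effect_class is EffectClass.SPLICE_PROX)
    return burden_from_counts(n_total, n_nonsense, n_splice)
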