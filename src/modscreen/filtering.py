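"""Homozygous-variant filtering for WGS call sets from mutagenized strains.

A call from a suppressor strain passes when all four predicates hold, in
this fixed order (a rejected call is tallied once, under the first
criterion it fails):

1. read depth strictly greater than ``min_depth_exclusive`` (default 5)
2. allele fraction strictly greater than ``min_af_exclusive`` (default 0.9,
   selecting homozygous calls)
3. position in a coding region or within ``splice_window_nt`` (default 10)
   of a splice junction; UTR positions inside the transcript also pass when
   ``include_utr`` is set (the default — 5'UTR suppressors are real)
4. de novo: no parental call matches on (chromosome, position, ref, alt)

Both thresholds are strict inequalities (depth 5 fails, allele fraction
0.9 fails).

The module also reports whether the strain still carries the primary
lesion. Calls are made against the wildtype reference, so a strain with no
call at the primary site is wildtype there — i.e. reverted (or a wildtype
contaminant; the two are separated downstream by background load).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import ConfigError, ModelError
from .io import PrimaryAllele, TranscriptModel, VariantCall


class RegionClass(str, Enum):
    CODING = "CODING"
    SPLICE_PROX = "SPLICE_PROX"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"


#: priority order when transcripts overlap (highest first)
REGION_PRIORITY = (
    RegionClass.CODING,
    RegionClass.SPLICE_PROX,
    RegionClass.UTR5,
    RegionClass.UTR3,
    RegionClass.INTRONIC,
    RegionClass.INTERGENIC,
)

_RANK = {r: i for i, r in enumerate(REGION_PRIORITY)}


class RetentionStatus(str, Enum):
    RETAINED = "RETAINED"
    REVERTED = "REVERTED"
    NOT_OBSERVED = "NOT_OBSERVED"


#: rejection-tally keys, in attribution order
CRITERIA = ("depth", "allele_fraction", "region", "de_novo")


@dataclass(frozen=True)
class FilterConfig:
    min_depth_exclusive: int = 5
    min_af_exclusive: float = 0.9
    splice_window_nt: int = 10
    include_utr: bool = True
    require_de_novo: bool = True

    def __post_init__(self) -> None:
        if self.splice_window_nt < 0:
            raise ConfigError("splice_window_nt must be >= 0")
        if not 0.0 <= self.min_af_exclusive < 1.0:
            raise ConfigError("min_af_exclusive must be in [0, 1)")


@dataclass
class FilterResult:
    passing: list[VariantCall]
    rejection_tally: dict[str, int]
    retention_status: RetentionStatus

    @property
    def n_passing(self) -> int:
        return len(self.passing)


def _classify_one(tr: TranscriptModel, position: int, window: int) -> RegionClass:
    """Region class of a position relative to a single transcript."""
    lo, hi = tr.span
    if not lo <= position <= hi:
        return RegionClass.INTERGENIC

    cds_lo, cds_hi = tr.cds_span

    exon_index = None
    for i, (s, e) in enumerate(tr.exons):
        if s <= position <= e:
            exon_index = i
            break

    # near an exon/intron junction? internal exon edges only; the window
    # covers both sides: w exonic bases and w intronic bases at each edge
    near_junction = False
    for i, (s, e) in enumerate(tr.exons):
        if i > 0 and s - window <= position <= s + window - 1:
            near_junction = True
        if i < len(tr.exons) - 1 and e - window + 1 <= position <= e + window:
            near_junction = True

    if exon_index is not None:
        if cds_lo <= position <= cds_hi:
            return RegionClass.CODING
        if near_junction:
            return RegionClass.SPLICE_PROX
        # exonic but outside the CDS: UTR, strand-aware
        before_cds = position < cds_lo
        if (tr.strand == "+") == before_cds:
            return RegionClass.UTR5
        return RegionClass.UTR3
    # intronic
    if near_junction:
        return RegionClass.SPLICE_PROX
    return RegionClass.INTRONIC


def classify_region(
    transcripts: Sequence[TranscriptModel],
    chromosome: str,
    position: int,
    splice_window_nt: int = 10,
) -> RegionClass:
    """Highest-priority region class of a position across transcripts.

    CODING > SPLICE_PROX > UTR5 > UTR3 > INTRONIC > INTERGENIC; positions off
    every transcript are INTERGENIC.
    """
    if position < 1:
        raise ModelError(f"position {position} < 1")
    best = RegionClass.INTERGENIC
    for tr in transcripts:
        if tr.chromosome != chromosome:
            continue
        cls = _classify_one(tr, position, splice_window_nt)
        if _RANK[cls] < _RANK[best]:
            best = cls
    return best


def _region_passes(region: RegionClass, config: FilterConfig) -> bool:
    if region in (RegionClass.CODING, RegionClass.SPLICE_PROX):
        return True
    if config.include_utr and region in (RegionClass.UTR5, RegionClass.UTR3):
        return True
    return False


def retention_status(
    calls: Sequence[VariantCall], primary: PrimaryAllele
) -> RetentionStatus:
    """Primary-lesion status from the strain's raw calls.

    RETAINED when the mutant allele is called; REVERTED when the site has no
    call at all (wildtype against the reference); NOT_OBSERVED when the site
    carries some third allele.
    """
    at_site = [
        c
        for c in calls
        if c.chromosome == primary.chromosome and c.position == primary.position
    ]
    for call in at_site:
        if (
            call.ref_base == primary.wildtype_base
            and call.alt_base == primary.mutant_base
        ):
            return RetentionStatus.RETAINED
    if at_site:
        return RetentionStatus.NOT_OBSERVED
    return RetentionStatus.REVERTED


def apply_filters(
    calls: Sequence[VariantCall],
    parental_calls: Sequence[VariantCall],
    transcripts: Sequence[TranscriptModel],
    config: FilterConfig,
    primary: PrimaryAllele,
) -> FilterResult:
    """Apply the four-predicate filter to one strain's call set."""
    if not transcripts:
        raise ConfigError("region filtering requires at least one transcript model")
    parental_keys = {c.key for c in parental_calls}
    passing: list[VariantCall] = []
    tally = {name: 0 for name in CRITERIA}
    for call in calls:
        if not call.read_depth > config.min_depth_exclusive:
            tally["depth"] += 1
            continue
        if not call.allele_fraction > config.min_af_exclusive:
            tally["allele_fraction"] += 1
            continue
        region = classify_region(
            transcripts, call.chromosome, call.position, config.splice_window_nt
        )
        if not _region_passes(region, config):
            tally["region"] += 1
            continue
        if config.require_de_novo and call.key in parental_keys:
            tally["de_novo"] += 1
            continue
        passing.append(call)
    return FilterResult(
        passing=passing,
        rejection_tally=tally,
        retention_status=retention_status(calls, primary),
    )
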