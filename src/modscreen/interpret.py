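"""Post-annotation inference: mutational spectra, revertant validation,
recurrence and saturation signals.

Substitutions are classified into the six strand-collapsed classes (a C>T
call and a G>A call are the same chemical event on opposite strands). A
"reverted" strain is accepted as a true revertant only when it carries a
genome-wide mutagen background — a wildtype contaminant has none — and that
background matches the mutagen's spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import EffectAnnotation
from .errors import DomainError, UsageError
from .filtering import FilterResult, RetentionStatus
from .io import PrimaryAllele, VariantCall

#: the six strand-collapsed single-nucleotide substitution classes
SUBSTITUTION_CLASSES = (
    "G:C>A:T",
    "A:T>G:C",
    "G:C>T:A",
    "G:C>C:G",
    "A:T>T:A",
    "A:T>C:G",
)

#: per-class map from plus-strand ref base to alt base
CLASS_SUBSTITUTIONS = {
    "G:C>A:T": {"G": "A", "C": "T"},
    "A:T>G:C": {"A": "G", "T": "C"},
    "G:C>T:A": {"G": "T", "C": "A"},
    "G:C>C:G": {"G": "C", "C": "G"},
    "A:T>T:A": {"A": "T", "T": "A"},
    "A:T>C:G": {"A": "C", "T": "G"},
}

_PURINES = {"A", "G"}

_CLASS_OF = {
    (ref, alt): cls
    for cls, subs in CLASS_SUBSTITUTIONS.items()
    for ref, alt in subs.items()
}


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, str]:
    """(transition|transversion, strand-collapsed class) for a substitution."""
    if ref_base == alt_base:
        raise DomainError("ref equals alt")
    try:
        cls = _CLASS_OF[(ref_base, alt_base)]
    except KeyError:
        raise DomainError(f"invalid substitution {ref_base}>{alt_base}") from None
    kind = (
        "transition"
        if (ref_base in _PURINES) == (alt_base in _PURINES)
        else "transversion"
    )
    return kind, cls


# ---------------------------------------------------------------------------
# Spectrum consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumFit:
    consistent_fraction: float
    statistic: float
    df: int
    pvalue: float
    class_counts: dict[str, int]


def spectrum_consistency(
    calls: Sequence[VariantCall],
    spectrum,
    weight_floor: float = 0.0,
) -> SpectrumFit:
    """How well a call set matches a mutagen spectrum.

    ``consistent_fraction`` is the share of calls whose collapsed class has
    spectrum weight above ``weight_floor``; the goodness-of-fit statistic is
    the multinomial chi-square of class counts against the spectrum over its
    nonzero classes (df = nonzero classes − 1).
    """
    if not calls:
        raise DomainError("spectrum_consistency requires a non-empty call list")
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    for call in calls:
        _, cls = classify_substitution(call.ref_base, call.alt_base)
        counts[cls] += 1
    weights = spectrum.weights
    n = len(calls)
    consistent = sum(c for cls, c in counts.items() if weights.get(cls, 0.0) > weight_floor)

    nonzero = [cls for cls in SUBSTITUTION_CLASSES if weights.get(cls, 0.0) > 0.0]
    stray = n - sum(counts[cls] for cls in nonzero)
    if stray > 0:
        # observations in zero-probability classes: the fit is unconditionally rejected
        statistic, pvalue = float("inf"), 0.0
    else:
        observed = np.array([counts[cls] for cls in nonzero], dtype=float)
        expected = np.array([n * weights[cls] for cls in nonzero])
        statistic, pvalue = stats.chisquare(observed, expected)
        statistic, pvalue = float(statistic), float(pvalue)
    return SpectrumFit(
        consistent_fraction=consistent / n,
        statistic=statistic,
        df=len(nonzero) - 1,
        pvalue=pvalue,
        class_counts=counts,
    )


# ---------------------------------------------------------------------------
# Revertant vs contamination
# ---------------------------------------------------------------------------


class RevertantStatus(str, Enum):
    TRUE_REVERTANT = "TRUE_REVERTANT"
    SUSPECTED_CONTAMINATION = "SUSPECTED_CONTAMINATION"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class RevertantVerdict:
    status: RevertantStatus
    background_load: int
    spectrum_consistent_fraction: float


def validate_revertant(
    filter_result: FilterResult,
    primary: PrimaryAllele,
    spectrum,
    min_load: int = 20,
    min_fraction: float = 0.9,
) -> RevertantVerdict:
    """Decide whether a reverted strain is a true revertant.

    A wildtype contaminant shows (near) zero filtered background; a true
    revertant carries a full mutagen background consistent with the spectrum.
    """
    if filter_result.retention_status is not RetentionStatus.REVERTED:
        raise UsageError(
            "validate_revertant applies only to strains with retention_status REVERTED"
        )
    background = [
        c
        for c in filter_result.passing
        if not (c.chromosome == primary.chromosome and c.position == primary.position)
    ]
    load = len(background)
    if load == 0:
        return RevertantVerdict(RevertantStatus.SUSPECTED_CONTAMINATION, 0, 0.0)
    fraction = spectrum_consistency(background, spectrum).consistent_fraction
    if load >= min_load and fraction >= min_fraction:
        status = RevertantStatus.TRUE_REVERTANT
    elif load < min_load:
        status = RevertantStatus.SUSPECTED_CONTAMINATION
    else:
        status = RevertantStatus.AMBIGUOUS
    return RevertantVerdict(status, load, fraction)


# ---------------------------------------------------------------------------
# Recurrence and saturation
# ---------------------------------------------------------------------------


@dataclass
class RecurrenceReport:
    by_position: dict[tuple[str, int, str, str], list[str]]
    by_codon: dict[tuple[str, int], list[tuple[str, str]]]
    multi_hit_positions: int
    multi_hit_codons: int
    prior_overlap: int


def recurrence_report(
    annotations: Sequence[EffectAnnotation],
    prior_sites: Optional[Iterable[tuple[str, int]]] = None,
) -> RecurrenceReport:
    """Group target-gene annotations by exact variant and by affected codon."""
    by_position: dict[tuple[str, int, str, str], list[str]] = {}
    by_codon: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for ann in annotations:
        v = ann.variant
        by_position.setdefault(v.key, [])
        if v.strain_id not in by_position[v.key]:
            by_position[v.key].append(v.strain_id)
        if ann.codon_index is not None:
            key = (ann.gene_id, ann.codon_index)
            by_codon.setdefault(key, []).append((v.strain_id, ann.protein_token))
    multi_positions = sum(1 for strains in by_position.values() if len(strains) >= 2)
    multi_codons = sum(
        1
        for hits in by_codon.values()
        if len({strain for strain, _ in hits}) >= 2
    )
    prior = set(prior_sites or ())
    overlap = sum(1 for (chrom, pos, _, _) in by_position if (chrom, pos) in prior)
    return RecurrenceReport(
        by_position=by_position,
        by_codon=by_codon,
        multi_hit_positions=multi_positions,
        multi_hit_codons=multi_codons,
        prior_overlap=overlap,
    )


@dataclass(frozen=True)
class SaturationSignals:
    revertant_observed: bool
    recurrent_position: bool
    recurrent_codon: bool
    prior_overlap: int
    summary: str


def saturation_signals(
    report: RecurrenceReport, revertant_observed: bool
) -> SaturationSignals:
    """Qualitative screen-saturation signals.

    No formal saturation probability is estimated; the signals are the ones a
    screen reads off its intragenic spectrum: a rare reversion event, the
    same position hit in multiple strains, the same codon hit with different
    changes, and overlap with previously published sites.
    """
    pos = report.multi_hit_positions >= 1
    codon = report.multi_hit_codons >= 1
    parts = []
    parts.append(
        "revertant observed" if revertant_observed else "no revertant observed"
    )
    parts.append(
        f"{report.multi_hit_positions} position(s) hit in >=2 strains"
        if pos
        else "no position hit more than once"
    )
    parts.append(
        f"{report.multi_hit_codons} codon(s) hit in >=2 strains"
        if codon
        else "no codon hit more than once"
    )
    parts.append(f"{report.prior_overlap} site(s) overlapping prior screens")
    n_signals = sum([revertant_observed, pos, codon])
    verdict = (
        "screen is likely nearing saturation"
        if n_signals >= 2
        else "no strong evidence of saturation"
    )
    summary = "; ".join(parts) + f" -> {verdict}"
    return SaturationSignals(
        revertant_observed=revertant_observed,
        recurrent_position=pos,
        recurrent_codon=codon,
        prior_overlap=report.prior_overlap,
        summary=summary,
    )
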