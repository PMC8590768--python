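"""Sanger-vs-WGS cost and hands-on-time model for intragenic genotyping.

Defaults encode the study's CAD figures: Sanger at $0.40 (primers) + $5.00
(PCR) + $12.00 (purification) + $64.00 (sequencing submission) per strain
with ~2.5 days hands-on for a 100-strain screen; WGS at $14 (gDNA
extraction) + $200 (sequencing) per strain with ~7 hours hands-on at the
same scale. Costs are exact decimals; totals are linear in the strain count
and in each component. Hands-on times are stored as totals at a reference
strain count and scaled linearly — an approximation, since batching makes
real hands-on time sublinear.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping

from .errors import ConfigError

SANGER_COMPONENTS = {
    "primers": Decimal("0.40"),
    "pcr_reaction": Decimal("5.00"),
    "dna_purification": Decimal("12.00"),
    "sanger_submission": Decimal("64.00"),
}

WGS_COMPONENTS = {
    "gdna_extraction": Decimal("14.00"),
    "wgs_sequencing": Decimal("200.00"),
}

REFERENCE_N_STRAINS = 100
SANGER_HOURS_AT_REFERENCE = Decimal("60")  # 2.5 working days
WGS_HOURS_AT_REFERENCE = Decimal("7")

CAVEATS = (
    "Sanger: cheaper per strain for the target locus alone; samples are "
    "largely analyzed individually; cost grows with gene size and primer "
    "sets; no information on extragenic variants or genomic background.",
    "WGS: higher per-strain cost; batchable extractions and rapid in-silico "
    "screening; reveals retention of the primary lesion, intragenic and "
    "extragenic variants, and genome-wide burden in one pass; needs more "
    "starting material, which weak suppressors may not provide.",
)


@dataclass(frozen=True)
class CostProfile:
    method: str  # SANGER | WGS
    per_strain_components: Mapping[str, Decimal]
    hands_on_hours_at_reference: Decimal
    n_strains: int
    reference_n_strains: int = REFERENCE_N_STRAINS

    def __post_init__(self) -> None:
        if self.n_strains < 0:
            raise ConfigError("n_strains must be >= 0")
        if any(v < 0 for v in self.per_strain_components.values()):
            raise ConfigError("component costs must be >= 0")

    @property
    def per_strain_cost(self) -> Decimal:
        return sum(self.per_strain_components.values(), Decimal(0))

    @property
    def hands_on_hours(self) -> Decimal:
        """Total hands-on hours, scaled linearly from the reference count."""
        return (
            self.hands_on_hours_at_reference
            * Decimal(self.n_strains)
            / Decimal(self.reference_n_strains)
        )


def sanger_profile(n_strains: int = REFERENCE_N_STRAINS, **overrides) -> CostProfile:
    components = dict(SANGER_COMPONENTS)
    components.update({k: Decimal(str(v)) for k, v in overrides.items()})
    return CostProfile("SANGER", components, SANGER_HOURS_AT_REFERENCE, n_strains)


def wgs_profile(n_strains: int = REFERENCE_N_STRAINS, **overrides) -> CostProfile:
    components = dict(WGS_COMPONENTS)
    components.update({k: Decimal(str(v)) for k, v in overrides.items()})
    return CostProfile("WGS", components, WGS_HOURS_AT_REFERENCE, n_strains)


def total_cost(profile: CostProfile) -> Decimal:
    """n_strains x sum of per-strain components, exact decimal arithmetic."""
    return Decimal(profile.n_strains) * profile.per_strain_cost


@dataclass(frozen=True)
class CostComparison:
    sanger: CostProfile
    wgs: CostProfile
    sanger_total: Decimal
    wgs_total: Decimal
    caveats: tuple[str, ...] = CAVEATS

    def render(self) -> str:
        lines = [
            f"n_strains: {self.sanger.n_strains}",
            f"Sanger: {self.sanger_total} CAD total "
            f"({self.sanger.per_strain_cost}/strain), "
            f"~{self.sanger.hands_on_hours} h hands-on",
            f"WGS:    {self.wgs_total} CAD total "
            f"({self.wgs.per_strain_cost}/strain), "
            f"~{self.wgs.hands_on_hours} h hands-on",
        ]
        lines += [f"* {c}" for c in self.caveats]
        return "\n".join(lines)


def compare(sanger: CostProfile, wgs: CostProfile) -> CostComparison:
    """Side-by-side totals and hands-on times for equal strain counts."""
    if sanger.n_strains != wgs.n_strains:
        raise ConfigError(
            f"profiles compare unequal screens: {sanger.n_strains} vs {wgs.n_strains}"
        )
    return CostComparison(
        sanger=sanger,
        wgs=wgs,
        sanger_total=total_cost(sanger),
        wgs_total=total_cost(wgs),
    )
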