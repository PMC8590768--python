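"""Synthetic EMS/ENU suppressor-screen generator.

Emulates the study design end to end so every downstream stage has ground
truth: a mutagenized strain carries the primary temperature-sensitive lesion
plus a genome-wide background of substitutions drawn from its mutagen's
strand-collapsed spectrum; intragenic-suppressor strains additionally carry
one planted in-gene variant; a revertant carries the wildtype base at the
primary site with a full mutagen background; a wildtype contaminant carries
neither. Homozygous calls get moderate read depth (negative binomial) and
allele fraction concentrated near 1 (Beta).

Spectrum defaults are qualitative conventions, config-overridable: EMS is
dominated by G:C>A:T transitions; ENU favours A:T>T:A transversions plus
transitions. Background substitutions are placed, by default, only in the
regions the downstream filter keeps (coding / splice-proximal / UTR), spread
over decoy genes scattered along the chromosome; a flag enables genome-wide
placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import fixture as fx
from .errors import ConfigError, DomainError, SimulationError
from .interpret import CLASS_SUBSTITUTIONS, SUBSTITUTION_CLASSES
from .io import (
    Genome,
    PrimaryAllele,
    TranscriptModel,
    VariantCall,
    write_fasta,
    write_gff3,
    write_manifest,
    write_vcf,
)
from .phenotype import (
    HatchPlate,
    PopulationPlate,
    write_hatch_tsv,
    write_population_tsv,
)

AF_MEAN_HOMOZYGOUS = 0.97
DEPTH_DISPERSION = 10.0


# ---------------------------------------------------------------------------
# Mutagen spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutagenSpectrum:
    """Probabilities over the six strand-collapsed substitution classes."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ConfigError(f"unknown substitution classes {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("spectrum weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"spectrum weights sum to {total}, expected 1")

    def weight_array(self) -> np.ndarray:
        return np.array([self.weights.get(c, 0.0) for c in SUBSTITUTION_CLASSES])


def default_spectrum(mutagen_name: str) -> MutagenSpectrum:
    """Built-in spectrum for EMS, ENU or the EMS+ENU cocktail."""
    if mutagen_name == "EMS":
        weights = {c: 0.15 / 5 for c in SUBSTITUTION_CLASSES}
        weights["G:C>A:T"] = 0.85
    elif mutagen_name == "ENU":
        rest = ("G:C>T:A", "G:C>C:G", "A:T>C:G")
        weights = {c: 0.20 / 3 for c in rest}
        weights.update({"A:T>T:A": 0.30, "A:T>G:C": 0.25, "G:C>A:T": 0.25})
    elif mutagen_name == "EMS+ENU":
        ems = default_spectrum("EMS").weights
        enu = default_spectrum("ENU").weights
        weights = {c: (ems[c] + enu[c]) / 2 for c in SUBSTITUTION_CLASSES}
    else:
        raise ConfigError(f"unknown mutagen {mutagen_name!r}")
    return MutagenSpectrum(weights)


# ---------------------------------------------------------------------------
# Plans and strain records
# ---------------------------------------------------------------------------


class TruthLabel(str, Enum):
    INTRAGENIC_SUPPRESSOR = "INTRAGENIC_SUPPRESSOR"
    EXTRAGENIC_SUPPRESSOR = "EXTRAGENIC_SUPPRESSOR"
    REVERTANT = "REVERTANT"
    CONTAMINATION = "CONTAMINATION"


@dataclass(frozen=True)
class ScreenPlan:
    """Parameters of one simulated screen.

    The defaults emulate the study conditions: a filtered mutational load in
    the tens-to-hundreds per strain, ~12% of suppressor strains intragenic,
    reversion and contamination rare, homozygous calls at moderate depth.
    """

    n_strains: int = 50
    mutation_load_mean: float = 110.0
    fraction_intragenic: float = 0.12
    fraction_revertant: float = 0.02
    fraction_contamination: float = 0.02
    depth_mean: float = 30.0
    af_homozygous_concentration: float = 150.0
    seed: int = 0
    parental_background_count: int = 25
    stray_call_max: int = 3

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ConfigError("n_strains must be >= 1")
        if self.mutation_load_mean < 0:
            raise ConfigError("mutation_load_mean must be >= 0")
        fracs = (
            self.fraction_intragenic,
            self.fraction_revertant,
            self.fraction_contamination,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ConfigError("label fractions must lie in [0,1] and sum to <= 1")
        if self.depth_mean <= 0 or self.af_homozygous_concentration <= 0:
            raise ConfigError("depth_mean and af_homozygous_concentration must be > 0")


@dataclass
class SimulatedStrain:
    strain_id: str
    truth_label: TruthLabel
    planted_variant: Optional[VariantCall]
    calls: list[VariantCall]
    mutagen: str
    suppression_strength: float = 0.5


# ---------------------------------------------------------------------------
# Genomes and transcripts
# ---------------------------------------------------------------------------

_BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_genome(
    chrom_lengths: Mapping[str, int], gc_fraction: float, seed: int
) -> Genome:
    """Random genome with i.i.d. bases at the requested GC fraction."""
    if not 0 < gc_fraction < 1:
        raise ConfigError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p_at = (1 - gc_fraction) / 2
    p_gc = gc_fraction / 2
    sequences = {}
    for name, length in chrom_lengths.items():
        if length < 1:
            raise ConfigError(f"chromosome {name!r}: length must be >= 1")
        draws = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
        sequences[name] = _BASE_LOOKUP[draws].tobytes().decode("ascii")
    return Genome(sequences)


def apply_patches(genome: Genome, patches: Mapping[str, Mapping[int, str]]) -> Genome:
    """New genome with single-base patches applied (chrom -> {pos: base})."""
    sequences = dict(genome.sequences)
    for chrom, sites in patches.items():
        buf = bytearray(sequences[chrom], "ascii")
        for pos, base in sites.items():
            buf[pos - 1] = ord(base)
        sequences[chrom] = buf.decode("ascii")
    return Genome(sequences)


def random_transcript(
    rng: np.random.Generator,
    chromosome: str,
    start: int,
    gene_id: str,
    strand: str = "+",
    n_codons: Optional[int] = None,
    n_exons: Optional[int] = None,
) -> tuple[TranscriptModel, dict[int, str]]:
    """A random valid transcript plus the genome patches realising it.

    The returned patches write the transcript's cDNA (ATG .. sense codons ..
    stop, random UTRs) and canonical GT..AG intron dinucleotides onto the
    genome, so annotation of the patched genome is internally consistent.
    """
    n_codons = int(n_codons if n_codons is not None else rng.integers(60, 200))
    n_exons = int(n_exons if n_exons is not None else rng.integers(1, 5))
    utr5 = int(rng.integers(10, 60))
    utr3 = int(rng.integers(10, 60))
    total = utr5 + 3 * n_codons + utr3

    # split the cDNA into exons, then insert introns genomically
    cuts = sorted(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    bounds = [0, *map(int, cuts), total]
    exon_lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    intron_lengths = [int(rng.integers(50, 500)) for _ in range(n_exons - 1)]

    exons = []
    g = start
    for i, length in enumerate(exon_lengths):
        exons.append((g, g + length - 1))
        g += length
        if i < len(intron_lengths):
            g += intron_lengths[i]

    sense = np.array(fx._SENSE_CODONS)
    body = "".join(sense[rng.integers(0, len(sense), size=n_codons - 2)])
    cds = "ATG" + body + ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    utr_bases = _BASE_LOOKUP[rng.integers(0, 4, size=utr5 + utr3)].tobytes().decode()
    cdna = utr_bases[:utr5] + cds + utr_bases[utr5:]

    spliced = np.concatenate([np.arange(s, e + 1) for s, e in exons])
    if strand == "-":
        spliced = spliced[::-1]
        cdna_genomic = cdna.translate(str.maketrans("ACGT", "TGCA"))
    else:
        cdna_genomic = cdna
    patches = {int(pos): cdna_genomic[i] for i, pos in enumerate(spliced)}
    for (_, e), (s2, _) in zip(exons, exons[1:]):
        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
        patches[e + 1], patches[e + 2] = donor[0], donor[1]
        patches[s2 - 2], patches[s2 - 1] = acceptor[0], acceptor[1]

    transcript = TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chromosome=chromosome,
        strand=strand,
        exons=tuple(exons),
        cds_start_g=int(spliced[utr5]),
        cds_end_g=int(spliced[utr5 + 3 * n_codons - 1]),
    )
    return transcript, patches


def build_fixture_transcript() -> tuple[TranscriptModel, Genome]:
    """Re-export of the deterministic target-gene fixture."""
    return fx.build_fixture_transcript()


# ---------------------------------------------------------------------------
# Substitution placement
# ---------------------------------------------------------------------------


@dataclass
class SitePool:
    """Uniformly samplable set of genomic positions across chromosomes."""

    chroms: list[str]
    arrays: list[np.ndarray]  # 1-based positions per chromosome

    def __len__(self) -> int:
        return sum(len(a) for a in self.arrays)

    def sample(self, rng: np.random.Generator, k: int) -> list[tuple[str, int]]:
        total = len(self)
        sizes = np.array([len(a) for a in self.arrays])
        cum = np.cumsum(sizes)
        flat = rng.integers(0, total, size=k)
        out = []
        for f in flat:
            c = int(np.searchsorted(cum, f, side="right"))
            offset = f - (cum[c - 1] if c else 0)
            out.append((self.chroms[c], int(self.arrays[c][offset])))
        return out


def eligible_positions(
    genome: Genome,
    transcripts: Sequence[TranscriptModel],
    splice_window_nt: int = 10,
    genome_wide: bool = False,
) -> dict[str, SitePool]:
    """Site pools where mutations may land, split by reference base pair.

    By default only filter-surviving regions are eligible: exonic positions
    (coding + UTR) plus the first/last ``splice_window_nt`` bases of each
    intron. With ``genome_wide`` every position is eligible.
    """
    masks: dict[str, np.ndarray] = {}

    def mask_for(chrom: str) -> np.ndarray:
        if chrom not in masks:
            masks[chrom] = np.zeros(genome.length(chrom), dtype=bool)
        return masks[chrom]

    if genome_wide:
        for chrom in genome.sequences:
            mask_for(chrom)[:] = True
    else:
        w = splice_window_nt
        for tr in transcripts:
            mask = mask_for(tr.chromosome)
            for s, e in tr.exons:
                mask[s - 1 : e] = True
            for (_, e), (s2, _) in zip(tr.exons, tr.exons[1:]):
                gs, ge = e + 1, s2 - 1  # intron bounds
                mask[gs - 1 : min(gs + w - 1, ge)] = True
                mask[max(ge - w + 1, gs) - 1 : ge] = True

    pools: dict[str, SitePool] = {}
    for pair, bases in (("GC", b"GC"), ("AT", b"AT")):
        chroms, arrays = [], []
        for chrom, mask in masks.items():
            seq = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
            hit = mask & ((seq == bases[0]) | (seq == bases[1]))
            positions = np.nonzero(hit)[0] + 1
            if len(positions):
                chroms.append(chrom)
                arrays.append(positions)
        pools[pair] = SitePool(chroms, arrays)
    return pools


def _pair_of_class(cls: str) -> str:
    return "GC" if cls.startswith("G:C") else "AT"


def simulate_substitutions(
    genome: Genome,
    spectrum: MutagenSpectrum,
    n: int,
    rng: np.random.Generator,
    sites: Optional[dict[str, SitePool]] = None,
) -> list[tuple[str, int, str, str]]:
    """Draw n substitutions: class from the spectrum, site uniform among
    reference bases compatible with the class. Returns (chrom, pos, ref, alt).
    """
    if sites is None:
        sites = eligible_positions(genome, (), genome_wide=True)
    weights = spectrum.weight_array()
    placeable = [
        c
        for c, w in zip(SUBSTITUTION_CLASSES, weights)
        if w > 0 and len(sites[_pair_of_class(c)]) > 0
    ]
    if not placeable:
        raise SimulationError(
            "spectrum incompatible with genome composition: no class placeable"
        )
    if abs(sum(spectrum.weights.get(c, 0.0) for c in placeable) - 1.0) > 1e-9:
        raise SimulationError(
            "spectrum assigns weight to classes with no compatible reference base"
        )
    class_counts = rng.multinomial(n, weights)
    out: list[tuple[str, int, str, str]] = []
    for cls, count in zip(SUBSTITUTION_CLASSES, class_counts):
        if count == 0:
            continue
        for chrom, pos in sites[_pair_of_class(cls)].sample(rng, int(count)):
            ref = genome.base(chrom, pos)
            out.append((chrom, pos, ref, CLASS_SUBSTITUTIONS[cls][ref]))
    return out


# ---------------------------------------------------------------------------
# Strains
# ---------------------------------------------------------------------------


def _draw_depth(rng: np.random.Generator, mean: float) -> int:
    p = DEPTH_DISPERSION / (DEPTH_DISPERSION + mean)
    return max(1, int(rng.negative_binomial(DEPTH_DISPERSION, p)))


def _draw_af(rng: np.random.Generator, concentration: float) -> float:
    a = concentration * AF_MEAN_HOMOZYGOUS
    b = concentration * (1 - AF_MEAN_HOMOZYGOUS)
    return round(float(np.clip(rng.beta(a, b), 0.0, 1.0)), 4)


def _call(
    rng: np.random.Generator,
    plan: ScreenPlan,
    strain_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
) -> VariantCall:
    return VariantCall(
        strain_id=strain_id,
        chromosome=chrom,
        position=pos,
        ref_base=ref,
        alt_base=alt,
        read_depth=_draw_depth(rng, plan.depth_mean),
        allele_fraction=_draw_af(rng, plan.af_homozygous_concentration),
    )


def simulate_strain(
    genome: Genome,
    transcripts: Sequence[TranscriptModel],
    primary: PrimaryAllele,
    spectrum: MutagenSpectrum,
    plan: ScreenPlan,
    truth_label: TruthLabel,
    strain_id: str,
    rng: Optional[np.random.Generator] = None,
    parental_background: Sequence[VariantCall] = (),
    sites: Optional[dict[str, SitePool]] = None,
    target_sites: Optional[dict[str, SitePool]] = None,
    mutagen: str = "EMS+ENU",
) -> SimulatedStrain:
    """Generate one strain's call set according to its ground-truth label."""
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    if primary.position > genome.length(primary.chromosome):
        raise DomainError("primary allele position not covered by the genome")
    if sites is None:
        sites = eligible_positions(genome, transcripts)
    calls: dict[tuple[str, int], VariantCall] = {}

    if truth_label is TruthLabel.CONTAMINATION:
        n_stray = int(rng.integers(0, plan.stray_call_max + 1))
        for chrom, pos, ref, alt in simulate_substitutions(
            genome, spectrum, n_stray, rng, sites
        ):
            calls[(chrom, pos)] = _call(rng, plan, strain_id, chrom, pos, ref, alt)
        return SimulatedStrain(strain_id, truth_label, None, list(calls.values()), mutagen)

    # mutagen background
    n_background = int(rng.poisson(plan.mutation_load_mean))
    for chrom, pos, ref, alt in simulate_substitutions(
        genome, spectrum, n_background, rng, sites
    ):
        if (chrom, pos) == (primary.chromosome, primary.position):
            continue
        calls.setdefault(
            (chrom, pos), _call(rng, plan, strain_id, chrom, pos, ref, alt)
        )

    # shared parental background (depth/AF re-drawn per strain)
    for pc in parental_background:
        calls[(pc.chromosome, pc.position)] = _call(
            rng, plan, strain_id, pc.chromosome, pc.position, pc.ref_base, pc.alt_base
        )

    planted: Optional[VariantCall] = None
    if truth_label is TruthLabel.INTRAGENIC_SUPPRESSOR:
        pool_sites = target_sites if target_sites is not None else sites
        for _ in range(200):
            cands = simulate_substitutions(genome, spectrum, 1, rng, pool_sites)
            chrom, pos, ref, alt = cands[0]
            if (chrom, pos) != (primary.chromosome, primary.position):
                planted = _call(rng, plan, strain_id, chrom, pos, ref, alt)
                break
        else:  # pragma: no cover - requires a pathological target gene
            raise SimulationError("could not place an intragenic variant")
        calls[(planted.chromosome, planted.position)] = planted

    if truth_label is not TruthLabel.REVERTANT:
        calls[(primary.chromosome, primary.position)] = _call(
            rng,
            plan,
            strain_id,
            primary.chromosome,
            primary.position,
            primary.wildtype_base,
            primary.mutant_base,
        )
    # revertant: no call at the primary site (wildtype against the reference)

    ordered = sorted(calls.values(), key=lambda c: (c.chromosome, c.position))
    return SimulatedStrain(strain_id, truth_label, planted, ordered, mutagen)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotype(
    truth_label: TruthLabel,
    suppression_strength: float,
    n_plates: int,
    seed: int,
    strain_id: str = "SIM",
    brood_mean: float = 200.0,
    horizon: int = 30,
) -> tuple[list[HatchPlate], list[PopulationPlate]]:
    """Hatching and population plates for one strain.

    Eggs laid per day are Poisson around a quarter of the brood mean over the
    4-day assay; each egg hatches with probability ``suppression_strength``.
    The population plate runs a daily branching process: hatched worms reach
    L4 one day later, adults lay for four days, hatched progeny are fertile
    with the same probability (weakly suppressed escapers are sterile), and
    plates are censored at the 30-day horizon.
    """
    if not 0.0 <= suppression_strength <= 1.0:
        raise ConfigError("suppression_strength must lie in [0, 1]")
    if n_plates < 1:
        raise ConfigError("n_plates must be >= 1")
    rng = np.random.default_rng(seed)
    return (
        [
            _hatch_plate(rng, strain_id, f"H{i+1:02d}", suppression_strength, brood_mean)
            for i in range(n_plates)
        ],
        [
            _population_plate(rng, strain_id, f"P{i+1:02d}", suppression_strength, horizon)
            for i in range(n_plates)
        ],
    )


def _hatch_plate(
    rng: np.random.Generator,
    strain_id: str,
    plate_id: str,
    s: float,
    brood_mean: float,
) -> HatchPlate:
    days = []
    for _ in range(4):
        laid = int(rng.poisson(brood_mean / 4))
        hatched = int(rng.binomial(laid, s)) if laid else 0
        days.append((laid, hatched))
    return HatchPlate(strain_id=strain_id, plate_id=plate_id, days=tuple(days))


_LIFESPAN_DAYS = 10
_ADULT_AGE = 2          # age (days post-hatch) at first egg lay
_LAYING_DAYS = 4
_L4_AGE = 1
_EGGS_PER_DAY = 50
_POPULATION_CAP = 400
_ESTABLISHED = 200


def _population_plate(
    rng: np.random.Generator,
    strain_id: str,
    plate_id: str,
    s: float,
    horizon: int,
) -> PopulationPlate:
    # cohorts: age -> [fertile, sterile]; founder plated as a young adult
    cohorts: dict[int, list[int]] = {_ADULT_AGE: [1, 0]}
    pending_fertile = pending_sterile = 0
    daily = []
    death_day = None
    for day in range(1, horizon + 1):
        if pending_fertile or pending_sterile:
            slot = cohorts.setdefault(0, [0, 0])
            slot[0] += pending_fertile
            slot[1] += pending_sterile
            pending_fertile = pending_sterile = 0
        viable = sum(f + st for f, st in cohorts.values())
        l4plus = sum(f + st for age, (f, st) in cohorts.items() if age >= _L4_AGE)
        daily.append((day, viable, l4plus))
        if viable == 0:
            death_day = day
            break
        if viable >= _ESTABLISHED:
            # a population this far past the 50-worm metrics persists; carry
            # steady counts to the horizon instead of simulating turnover
            for later in range(day + 1, horizon + 1):
                daily.append((later, viable, viable))
            break
        laying = sum(
            f for age, (f, _) in cohorts.items()
            if _ADULT_AGE <= age < _ADULT_AGE + _LAYING_DAYS
        )
        if laying:
            eggs = int(rng.poisson(laying * _EGGS_PER_DAY))
            hatched = int(rng.binomial(eggs, s)) if eggs else 0
            # bound the tracked population: hatchlings beyond the cap's
            # headroom are not followed (metrics saturate well below it)
            hatched = min(hatched, max(0, _POPULATION_CAP - viable))
            pending_fertile = int(rng.binomial(hatched, s)) if hatched else 0
            pending_sterile = hatched - pending_fertile
        cohorts = {
            age + 1: counts
            for age, counts in cohorts.items()
            if age + 1 <= _LIFESPAN_DAYS
        }
    return PopulationPlate(
        strain_id=strain_id,
        plate_id=plate_id,
        daily=tuple(daily),
        death_day=death_day,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# Whole screens
# ---------------------------------------------------------------------------


@dataclass
class ScreenBundle:
    plan: ScreenPlan
    genome: Genome
    transcripts: list[TranscriptModel]
    primary: PrimaryAllele
    parental_calls: list[VariantCall]
    strains: list[SimulatedStrain]
    hatch_plates: list[HatchPlate]
    population_plates: list[PopulationPlate]


_MUTAGEN_CYCLE = ("EMS", "ENU", "EMS+ENU")


def simulate_screen(
    plan: ScreenPlan,
    genome: Optional[Genome] = None,
    transcripts: Optional[Sequence[TranscriptModel]] = None,
    primary: Optional[PrimaryAllele] = None,
    spectra: Optional[Mapping[str, MutagenSpectrum]] = None,
    n_decoy_genes: int = 300,
    n_plates_per_strain: int = 6,
    phenotype: bool = True,
) -> ScreenBundle:
    """Simulate a full screen against the target-gene fixture.

    By default the fixture transcript is the target and ``n_decoy_genes``
    random genes are scattered along the chromosome so the mutagen background
    lands genome-wide rather than piling into the target gene.
    """
    rng = np.random.default_rng(plan.seed)
    if genome is None or transcripts is None:
        target, genome = fx.build_fixture_transcript()
        transcripts = [target]
        patches: dict[int, str] = {}
        lo, hi = target.span
        g_len = genome.length(target.chromosome)
        for i in range(n_decoy_genes):
            for _ in range(50):
                start = int(rng.integers(1, g_len - 10_000))
                if not (lo - 10_000 < start < hi + 2_000):
                    break
            strand = "+" if rng.random() < 0.5 else "-"
            tr, p = random_transcript(
                rng, target.chromosome, start, gene_id=f"dgn-{i+1}", strand=strand
            )
            if any(
                t.span[0] - 600 <= tr.span[1] and tr.span[0] <= t.span[1] + 600
                for t in transcripts
            ):
                continue  # overlapping decoy: skip rather than entangle models
            transcripts = [*transcripts, tr]
            patches.update(p)
        genome = apply_patches(genome, {target.chromosome: patches})
    transcripts = list(transcripts)
    if primary is None:
        primary = fx.fixture_primary_allele()
    if spectra is None:
        spectra = {m: default_spectrum(m) for m in _MUTAGEN_CYCLE}

    sites = eligible_positions(genome, transcripts)
    target_tr = [t for t in transcripts if t.gene_id == primary.gene_id]
    if not target_tr:
        raise ConfigError(f"no transcript model for target gene {primary.gene_id!r}")
    target_sites = eligible_positions(genome, target_tr)

    # label assignment: deterministic counts, shuffled order
    n = plan.n_strains
    n_int = round(plan.fraction_intragenic * n)
    n_rev = round(plan.fraction_revertant * n)
    n_con = round(plan.fraction_contamination * n)
    labels = (
        [TruthLabel.INTRAGENIC_SUPPRESSOR] * n_int
        + [TruthLabel.REVERTANT] * n_rev
        + [TruthLabel.CONTAMINATION] * n_con
    )
    labels += [TruthLabel.EXTRAGENIC_SUPPRESSOR] * (n - len(labels))
    rng.shuffle(labels)

    # shared parental background (the pre-mutagenesis strain's own variants)
    parental_rng = np.random.default_rng(rng.integers(0, 2**31))
    parental_background = [
        VariantCall("PARENTAL", chrom, pos, ref, alt, 30, 1.0)
        for chrom, pos, ref, alt in simulate_substitutions(
            genome,
            default_spectrum("EMS+ENU"),
            plan.parental_background_count,
            parental_rng,
            sites,
        )
        if (chrom, pos) != (primary.chromosome, primary.position)
    ]
    parental_calls = [
        *parental_background,
        VariantCall(
            "PARENTAL",
            primary.chromosome,
            primary.position,
            primary.wildtype_base,
            primary.mutant_base,
            30,
            1.0,
        ),
    ]

    strains: list[SimulatedStrain] = []
    hatch_plates: list[HatchPlate] = []
    population_plates: list[PopulationPlate] = []
    for i, label in enumerate(labels):
        strain_id = f"SIM{i+1:03d}"
        mutagen = _MUTAGEN_CYCLE[i % len(_MUTAGEN_CYCLE)]
        strain = simulate_strain(
            genome,
            transcripts,
            primary,
            spectra[mutagen],
            plan,
            label,
            strain_id,
            rng=rng,
            parental_background=parental_background,
            sites=sites,
            target_sites=target_sites,
            mutagen=mutagen,
        )
        if label is TruthLabel.REVERTANT:
            strength = 0.98
        elif label is TruthLabel.CONTAMINATION:
            strength = 0.90
        else:
            strength = float(rng.uniform(0.1, 0.95))
        strain.suppression_strength = round(strength, 3)
        strains.append(strain)
        if phenotype:
            hp, pp = simulate_phenotype(
                label,
                strain.suppression_strength,
                n_plates_per_strain,
                seed=int(rng.integers(0, 2**31)),
                strain_id=strain_id,
            )
            hatch_plates.extend(hp)
            population_plates.extend(pp)

    return ScreenBundle(
        plan=plan,
        genome=genome,
        transcripts=transcripts,
        primary=primary,
        parental_calls=parental_calls,
        strains=strains,
        hatch_plates=hatch_plates,
        population_plates=population_plates,
    )


def emit_screen(bundle: ScreenBundle, outdir, header_comment: str = "") -> None:
    """Write the screen bundle to disk in the package's interchange formats:
    genome FASTA, gene-model GFF3, per-strain VCFs, manifest, truth table and
    phenotype TSVs."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    contigs = {c: len(s) for c, s in bundle.genome.sequences.items()}
    write_fasta(bundle.genome, outdir / "genome.fa")
    write_gff3(bundle.transcripts, outdir / "transcripts.gff3",
               header_comment=header_comment or None)
    vcf_header = [f"##modscreen={header_comment}"] if header_comment else []
    write_vcf(
        bundle.parental_calls,
        outdir / "vcf" / "PARENTAL.vcf",
        "PARENTAL",
        contigs,
        extra_header_lines=vcf_header,
    )
    manifest_rows = [
        {
            "strain_id": "PARENTAL",
            "mutagen": "none",
            "vcf_path": "vcf/PARENTAL.vcf",
            "role": "parental",
        }
    ]
    truth_rows = []
    for strain in bundle.strains:
        path = outdir / "vcf" / f"{strain.strain_id}.vcf"
        write_vcf(strain.calls, path, strain.strain_id, contigs,
                  extra_header_lines=vcf_header)
        manifest_rows.append(
            {
                "strain_id": strain.strain_id,
                "mutagen": strain.mutagen,
                "vcf_path": f"vcf/{strain.strain_id}.vcf",
                "role": "suppressor",
            }
        )
        pv = strain.planted_variant
        truth_rows.append(
            {
                "strain_id": strain.strain_id,
                "truth_label": strain.truth_label.value,
                "planted_chrom": pv.chromosome if pv else "",
                "planted_pos": pv.position if pv else "",
                "planted_ref": pv.ref_base if pv else "",
                "planted_alt": pv.alt_base if pv else "",
                "suppression_strength": strain.suppression_strength,
            }
        )
    write_manifest(pd.DataFrame(manifest_rows), outdir / "manifest.tsv",
                   header_comment=header_comment or None)
    with open(outdir / "truth.tsv", "w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        pd.DataFrame(truth_rows).to_csv(handle, sep="\t", index=False)
    write_hatch_tsv(bundle.hatch_plates, outdir / "hatch.tsv",
                    header_comment=header_comment or None)
    write_population_tsv(bundle.population_plates, outdir / "population.tsv",
                         header_comment=header_comment or None)
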