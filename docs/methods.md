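# Methods

This note documents the models, conventions and numerical choices behind
`modscreen`, in the order a screen's data flows through the package.

## Coordinates and gene models

All interfaces use 1-based inclusive coordinates (VCF/GFF3 convention); any
half-open arithmetic is internal. A `TranscriptModel` is an ordered list of
non-overlapping exon intervals plus the genomic positions of the first and
last coding base in transcript orientation (so `cds_start_g > cds_end_g` on
the minus strand); its spliced coding length must be a positive multiple
of 3. Chromosome names are taken verbatim from inputs — no `chr`
normalisation.

Genomic→cDNA mapping walks the spliced exon sequence in transcript order:
coding positions are 1-based from the first coding base, 5′UTR positions are
negative with no zero (HGVS convention), and intronic positions are anchored
to the nearest spliced neighbour with a signed offset (`c.939+3`,
`c.940-1`); ties between the two sides anchor to the donor (upstream) side.
3′UTR positions are classified but not given `c.*` numbering; their variants
are reported in `g.` notation. Codon arithmetic is
`codon = ceil(c/3)`, `offset = c − 3(codon−1)`.

## The target-gene fixture

The package ships no reference genome. Instead `modscreen.fixture`
deterministically reconstructs a plus-strand transcript on a synthetic
chromosome II whose coordinate system reproduces, exactly, the published
genomic/cDNA pairs of the screen's intragenic suppressor catalogue (the
three g−c offsets 5,649,909 / 5,649,992 / 5,652,014, with c.1 at
g = 5,649,774). Those offsets force three introns totalling 136, 83 and
2,022 nt; their placement inside the unconstrained gaps (between c.600/601,
c.939/940 and c.1262/1263) is this package's choice — the last intron must
lie upstream of c.1325 so the primary lesion at II:5,653,339 shares the
distal offset. Reference codons are pinned so each catalogued base change
forces its catalogued amino-acid change (codon 385 = GCT so c.1154C>T is
A385V, codon 442 = CCA so the primary lesion C→T at codon position 2 is
P442L, etc.); all other sequence (UTR filler, intron interiors, remaining
codons drawn from the 61 sense codons, flanking DNA) comes from a fixed-seed
generator, making the build byte-reproducible. Intron boundaries carry
canonical GT..AG dinucleotides.

## Variant filtering

A suppressor-strain call passes when all four predicates hold, evaluated in
a fixed order so rejection tallies are deterministic (each rejected call is
counted under the first criterion it fails):

1. `read_depth > 5` — strict, as is
2. `allele_fraction > 0.9` — strict; selects homozygous calls
3. region ∈ {coding, within ±10 nt of a splice junction} ∪ {5′/3′UTR if
   `include_utr`} — `include_utr` defaults to **true** because 5′UTR
   suppressors are a real outcome class of such screens; the strict
   coding/splice-only reading is available via `include_utr=false` (CLI
   `--strict-regions`)
4. de novo — no parental call matches the full (chromosome, position, ref,
   alt) tuple; a different alt at a parental site still counts as de novo

Region classes across overlapping transcripts resolve by priority
CODING > SPLICE_PROX > UTR5 > UTR3 > INTRONIC > INTERGENIC; an exonic coding
base near a junction is CODING.

Retention of the primary lesion is read from the *raw* calls, before
filtering, on the convention that calls are made against the wildtype
reference: the mutant allele called → RETAINED; no call at the site (the
site is wildtype) → REVERTED; a third allele called there → NOT_OBSERVED. A
wildtype contaminant therefore initially looks REVERTED; it is separated
from a true revertant downstream by its missing mutagen background.

## Effect annotation

Effects are computed by editing the affected codon of the spliced CDS
(strand-aware complementation on the minus strand) under the standard
genetic code, and are property-tested against a full-CDS re-translation
diff. The HGVS dialect is the compact one-letter style used in screen
reports (`p.A385V`, `p.H409=` for synonymous, `p.K533*` for nonsense,
`p.*534Q` for stop loss, start loss when codon 1 loses its Met); no
three-letter or parenthesised forms. Anomalous spacing in upstream sources
(`c. 937G > A`) is normalised to `c.937G>A`. Complex alleles join a strain's
in-gene protein tokens sorted by codon index (`P316H;S319A`). Burden
percentages are `100·count/total` rounded **half-up** to 2 decimals (5/188 →
2.66, 4/188 → 2.13, 1/70 → 1.43, 2/70 → 2.86); an empty set reports `None`
rather than 0.

## Screen interpretation

Substitutions collapse into the six strand-symmetric classes (C→T ≡ G→A)
because EMS/ENU chemistry does not distinguish strands. Spectrum consistency
of a call set is (a) the fraction of calls in classes with spectrum weight
above a floor (default 0) and (b) a multinomial chi-square against the
spectrum over its nonzero classes (df = classes − 1); observations in a
zero-weight class reject the fit outright.

A REVERTED strain is judged `TRUE_REVERTANT` when its filtered background
(excluding the primary site) has load ≥ `min_load` (default 20) **and**
spectrum-consistent fraction ≥ `min_fraction` (default 0.9);
`SUSPECTED_CONTAMINATION` when the load is below `min_load`; `AMBIGUOUS`
otherwise. The two thresholds are package conventions (the qualitative
evidence standard is "a full mutagen background present"), both config
keys.

Saturation is reported as qualitative signals, not a probability: a
reversion event observed, any position hit in ≥2 strains, any codon hit in
≥2 strains, and overlap with prior-screen sites. No unseen-allele estimator
is fitted.

## Phenotype assays

Hatching rate is pooled: `100 · Σ hatched / Σ laid` over up to 4 assay days,
to 2 decimals; zero eggs yields an undefined marker, not an exception.
Population plates record daily viable and L4-or-older counts; the three
events are first day viable ≥ 50, first day L4+ ≥ 50 ("equals 50" is
implemented as first crossing, since counts are daily snapshots), and
population death, all censored at the 30-day horizon. A plate that dies
before reaching a metric is censored for that metric at its death day — the
three outcomes are plotted as separate curves, not fitted as competing
risks. Curves are standard Kaplan–Meier product-limit estimates (computed
with lifelines; ties count events before censorings) reported in both S(t)
and the 1 − S(t) "% of plates reached" orientation.

## The synthetic screen generator

The generator's defaults are the study conditions it emulates: 50 strains
per screen, mean filtered mutational load 110 per strain (the catalogued
per-strain range is 47–188), 12% of strains intragenic, 2% revertant, 2%
contamination, read depth negative-binomial around 30 (dispersion 10, min
1), homozygous allele fraction Beta-distributed with mean 0.97 and
concentration 150, rounded to 4 decimals (which also makes VCF float32
round-trips exact). Mutagens cycle EMS → ENU → EMS+ENU across strains.

Spectrum defaults are qualitative conventions, overridable in config: EMS
0.85 on G:C>A:T with the rest uniform; ENU 0.30 A:T>T:A, 0.25 A:T>G:C, 0.25
G:C>A:T, rest uniform; the cocktail is their equal mixture. A substitution
is drawn class-first from the spectrum, then placed uniformly on a
compatible reference base, so class frequencies converge to the spectrum
regardless of genome composition.

Background mutations land only in filter-surviving regions (exons plus
splice windows) by default, spread across ~300 random decoy genes patched
onto the fixture chromosome so that only a small share of each strain's
background falls inside the target gene — emulating a genome-wide load seen
through the filter; a `genome_wide` flag lifts the restriction. All
non-contaminant strains share a 25-variant parental background (removed
downstream by the de novo criterion); contaminants carry at most 3 stray
calls and no primary lesion; revertants carry the wildtype base at the
primary site (no call) plus a full background; intragenic suppressors get
one planted spectrum-drawn variant inside the target transcript's
filter-eligible positions.

Phenotypes: eggs laid per day are Poisson around a quarter of a 200-egg
brood over 4 days; each egg hatches with probability `suppression_strength`.
The population plate is a daily branching process: a founder young adult,
eggs laid on 4 adult days (50/day expectation), eggs hatch the next day,
hatchlings are L4 one day post-hatch and adults a day later, lifespan 10
days, and hatched worms are themselves *fertile* with the same probability —
this sterile-escaper convention makes weakly suppressed populations die out
rather than limp along, matching the selection behaviour of the real assay.
Tracking is bounded: hatchlings beyond a 400-worm cap are not followed, and
a plate reaching 200 viable worms is deemed established and carried at
steady counts to the horizon (the metrics saturate at 50). Under this model
wildtype-like strains reach 50 viable worms by day ~2–3 and 50 L4+ a day
later, weak suppressors take ~5–9 days, and strengths below ~0.05 die out —
the qualitative pattern of the real assay. The generator does not emulate:
linkage or recombination, read-level noise (no FASTQ), realistic worm
demography, or genotype-specific brood sizes; passing tests therefore
validate the analysis logic, not biological effect sizes.

## Cost model

Costs are exact decimals (no floating-point cents): Sanger
0.40 + 5.00 + 12.00 + 64.00 = 81.40 CAD/strain; WGS 14 + 200 = 214
CAD/strain; totals are linear in strain count and in each component.
Hands-on times are stored as totals at a reference screen of 100 strains
(Sanger 60 h ≈ 2.5 working days; WGS 7 h) and scaled linearly — an
approximation, since batching makes real hands-on time sublinear in
practice.

## Pipeline and reproducibility

`simulate`, `analyze`, `phenotype`, `cost` and `report` are plain functions
over a YAML-backed `RunConfig`; the click CLI is a thin shell with exit
codes 0/1/2 for success/data error/config error. Every report file carries
`seed` and a 12-hex-digit hash of the scientific configuration (output and
input *locations* are excluded from the hash) in a header line, and a fixed
seed reproduces every emitted file byte for byte — VCFs included, since the
writer emits no timestamps.

## Problem sizes used in the test and acceptance suites

Oracle equivalences run at 1,000 random call sets (filter) and >10,000
random coding SNVs over five transcripts on both strands (annotator, against
full re-translation); spectrum convergence uses 100,000 draws on a 200 kb
genome; planted-variant recovery runs the full file-based pipeline on a
50-strain all-intragenic screen; phenotype calibration uses 200 plates.
These sizes give stable statistics while keeping the default suite fast.

## Known limitations

- Single-nucleotide substitutions only; indels are counted and skipped, and
  multi-nucleotide/frameshift effects are out of scope.
- One transcript per gene is assumed well-formed; overlapping transcripts
  are annotated independently and reports keep the highest-priority effect.
- 3′UTR variants get `g.` notation, not `c.*` numbering.
- The saturation report is deliberately qualitative; no capture-recapture
  estimate is made.
- The KM module reports curves only; no log-rank testing between strains.
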