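# modscreen

Identification and interpretation of **intragenic suppressor variants** from
whole-genome-sequenced, chemically mutagenized *C. elegans* strains.

## The problem

A suppressor screen starts from a strain carrying a deleterious primary
lesion — here a temperature-sensitive missense allele like *zyg-1(it25)*
(P442L), which is embryonic-lethal at the restrictive temperature — exposes
it to EMS and/or ENU, and selects survivors. Each surviving strain carries a
suppressing variant somewhere in its genome plus a few hundred passenger
mutations. Classically the in-gene (intragenic) suppressors are found by PCR
and Sanger sequencing of the target locus; sequencing whole genomes instead
reveals, in one pass, whether the primary lesion is retained, which in-gene
variants are present, the genome-wide mutational burden, and whether an
apparent revertant is real or just wildtype contamination.

`modscreen` implements the desk side of that workflow as a tested library
and CLI:

- **`modscreen.io`** — typed readers/writers for FASTA, GFF3, VCF v4.2
  (single-nucleotide substitutions; DP/AF from FORMAT, falling back to INFO)
  and the strain manifest.
- **`modscreen.filtering`** — the call filter: read depth > 5, allele
  fraction > 0.9 (homozygous selection), position in coding sequence or
  within ±10 nt of a splice junction (UTRs included by default), and de novo
  relative to the parental strain; plus primary-lesion retention status.
- **`modscreen.annotation`** — a from-scratch coding-effect annotator:
  genomic↔cDNA mapping over spliced transcripts, codon editing under the
  standard genetic code, compact HGVS-style output (`c.1154C>T` / `p.A385V`,
  `p.H409=`, `c.-4T>A`, `c.939+3G>A`), complex-allele labels
  (`P316H;S319A`) and nonsense/splice burden summaries.
- **`modscreen.interpret`** — strand-collapsed substitution spectra
  (transition/transversion classes), chi-square spectrum consistency,
  revertant-vs-contamination verdicts from background load, and screen
  saturation signals from recurrent positions/codons.
- **`modscreen.phenotype`** — hatching-rate and population assays with
  30-day censoring and Kaplan–Meier product-limit curves (via lifelines).
- **`modscreen.cost`** — the Sanger-vs-WGS cost/hands-on-time model.
- **`modscreen.simulate`** — a synthetic screen generator (mutagen spectra,
  decoy genes, planted suppressors, revertants, contamination, plate-level
  phenotypes) with ground-truth labels, so the whole pipeline is testable
  without sequencing data.

The key coordinate machinery: a coding position *c* maps to codon
`ceil(c/3)` with in-codon offset `c − 3(⌈c/3⌉ − 1)`; 5′UTR positions are
numbered −1, −2, … back from the first coding base; effects are computed by
editing the affected codon and comparing translations, which equals a full
CDS re-translation (property-tested).

## Worked example

Simulate a 12-strain screen against the built-in target-gene fixture, then
analyze it:

```python
from modscreen.config import RunConfig
from modscreen import pipeline

cfg = RunConfig(seed=11, outdir="out",
                simulate={"n_strains": 12, "fraction_intragenic": 0.25,
                          "fraction_revertant": 0.08,
                          "fraction_contamination": 0.08})
screen = pipeline.cmd_simulate(cfg)
cfg.paths = {"genome": f"{screen}/genome.fa", "gff3": f"{screen}/transcripts.gff3",
             "manifest": f"{screen}/manifest.tsv", "hatch": f"{screen}/hatch.tsv",
             "population": f"{screen}/population.tsv"}
pipeline.cmd_analyze(cfg)
pipeline.cmd_phenotype(cfg)
```

`out/analysis/variants_table.tsv` then contains one row per strain
(abridged):

```
strain  mutagen  n_filtered  allele_label       retention  flag
SIM001  EMS      114         C297Y;N471=;A491T  RETAINED
SIM008  ENU      90          R220S;S325C;E529=  RETAINED
SIM009  EMS+ENU  3                              REVERTED   SUSPECTED_CONTAMINATION
SIM012  EMS+ENU  96                             REVERTED   TRUE_REVERTANT
```

Reading it: `n_filtered` is the strain's filtered variant count;
`allele_label` joins its in-gene protein changes sorted by codon. SIM009
lacks the primary lesion *and* any mutagen background (3 stray calls), so it
is flagged as wildtype contamination; SIM012 also lost the primary lesion
but carries a full spectrum-consistent background (96 filtered variants), so
it is a true revertant. `out/analysis/interpretation.json` adds recurrence
and saturation signals, and `out/phenotype/strain_summary.tsv` gives
per-strain brood sizes, pooled hatching rates and the fraction of plates
reaching each population metric, with the product-limit curves in
`curves.tsv`.

The cost command prints the screening-economics comparison at 100 strains:

```
Sanger: 8140.00 CAD total (81.40/strain), ~60 h hands-on
WGS:    21400.00 CAD total (214.00/strain), ~7 h hands-on
```

The same flow is available from the shell:

```bash
modscreen --config run.yaml --outdir out simulate
modscreen --config run.yaml --outdir out report
```

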