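"""Domain types and readers/writers for the standard formats.

Coordinates are 1-based inclusive at every interface (VCF/GFF3 convention).
Only single-nucleotide substitutions are modelled; indels encountered in a
VCF are skipped and counted, never silently dropped.

Allele fractions are carried to 4 decimal places: pysam stores FORMAT floats
as float32, and rounding on both write and read makes VCF round-trips exact
at the interface.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ModelError

DNA_ALPHABET = frozenset("ACGTN")
BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

AF_DECIMALS = 4

MUTAGENS = ("EMS", "ENU", "EMS+ENU", "none")
MANIFEST_ROLES = ("suppressor", "parental", "control")
MANIFEST_COLUMNS = ("strain_id", "mutagen", "vcf_path", "role")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genome:
    """A reference genome: chromosome identifier -> uppercase DNA string."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ModelError("empty chromosome identifier")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-DNA characters: {sorted(bad)}"
                )

    def length(self, chromosome: str) -> int:
        return len(self.sequences[chromosome])

    def base(self, chromosome: str, position: int) -> str:
        """Base at a 1-based position."""
        return self.sequences[chromosome][position - 1]

    def slice(self, chromosome: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        return self.sequences[chromosome][start - 1 : end]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure, strand and CDS bounds for one transcript.

    ``exons`` are 1-based inclusive genomic intervals sorted ascending.
    ``cds_start_g``/``cds_end_g`` are the genomic positions of the first and
    last coding base *in transcript orientation*: on the minus strand
    ``cds_start_g > cds_end_g``.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_g: int
    cds_end_g: int

    def __post_init__(self) -> None:
        tid = self.transcript_id
        if self.strand not in ("+", "-"):
            raise ModelError(f"{tid}: strand must be '+' or '-'")
        if not self.exons:
            raise ModelError(f"{tid}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ModelError(f"{tid}: exon start {start} > end {end}")
            if start <= prev_end:
                raise ModelError(f"{tid}: exons overlap or are unsorted at {start}")
            prev_end = end
        lo, hi = self.cds_span
        for pos in (lo, hi):
            if not self._exonic(pos):
                raise ModelError(f"{tid}: CDS bound {pos} outside the exon union")
        if self.strand == "+" and self.cds_start_g > self.cds_end_g:
            raise ModelError(f"{tid}: plus-strand CDS bounds reversed")
        if self.strand == "-" and self.cds_start_g < self.cds_end_g:
            raise ModelError(f"{tid}: minus-strand CDS bounds reversed")
        n = self.coding_length
        if n <= 0 or n % 3 != 0:
            raise ModelError(f"{tid}: spliced coding length {n} is not a positive multiple of 3")

    # -- geometry helpers ---------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_span(self) -> tuple[int, int]:
        """Genomic (low, high) bounds of the CDS, strand-agnostic."""
        return min(self.cds_start_g, self.cds_end_g), max(self.cds_start_g, self.cds_end_g)

    def _exonic(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.exons)

    @property
    def coding_length(self) -> int:
        lo, hi = self.cds_span
        return sum(
            max(0, min(e, hi) - max(s, lo) + 1) for s, e in self.exons
        )

    def spliced_positions(self) -> np.ndarray:
        """Genomic positions of exonic bases in transcript (5'->3') order."""
        parts = [np.arange(s, e + 1) for s, e in self.exons]
        arr = np.concatenate(parts)
        return arr[::-1] if self.strand == "-" else arr

    def contains(self, chromosome: str, position: int) -> bool:
        lo, hi = self.span
        return chromosome == self.chromosome and lo <= position <= hi


@dataclass(frozen=True)
class VariantCall:
    """One strain's called single-nucleotide substitution."""

    strain_id: str
    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    read_depth: int
    allele_fraction: float

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ModelError(
                f"{self.chromosome}:{self.position}: bases must be A/C/G/T, "
                f"got {self.ref_base}/{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ModelError(f"{self.chromosome}:{self.position}: ref equals alt")
        if self.position < 1:
            raise ModelError(f"position {self.position} < 1")
        if self.read_depth < 0:
            raise ModelError("negative read depth")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ModelError(f"allele fraction {self.allele_fraction} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class PrimaryAllele:
    """The primary phenotype-causing lesion the screen suppresses."""

    gene_id: str
    chromosome: str
    position: int
    wildtype_base: str
    mutant_base: str
    protein_change: str

    def __post_init__(self) -> None:
        if self.wildtype_base == self.mutant_base:
            raise ModelError("primary allele: wildtype equals mutant base")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a FASTA file into a :class:`Genome` (order preserved, uppercased)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"FASTA record {record.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ncols = len(line.split("\t"))
            if ncols != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, found {ncols}")


def read_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse gene models from GFF3: one TranscriptModel per mRNA feature.

    CDS bounds are derived from the transcript's CDS features; TranscriptModel
    invariants (sorted non-overlapping exons, 3n coding length) are enforced.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: list[TranscriptModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        tid = mrna.id
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0] if parents else tid
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            raise ModelError(f"{tid}: mRNA has no exon features")
        if not cds:
            raise ModelError(f"{tid}: mRNA has no CDS features")
        lo = min(s for s, _ in cds)
        hi = max(e for _, e in cds)
        if mrna.strand == "-":
            cds_start_g, cds_end_g = hi, lo
        else:
            cds_start_g, cds_end_g = lo, hi
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tid,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds_start_g=cds_start_g,
                cds_end_g=cds_end_g,
            )
        )
    return transcripts


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | os.PathLike,
               header_comment: str | None = None) -> None:
    """Emit gene/mRNA/exon/CDS features readable by :func:`read_gff3`."""
    lines = ["##gff-version 3"]
    if header_comment:
        lines.append(f"# {header_comment}")
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tr in transcripts:
        by_gene.setdefault(tr.gene_id, []).append(tr)
    for gene_id, group in by_gene.items():
        chrom = group[0].chromosome
        strand = group[0].strand
        g_lo = min(tr.span[0] for tr in group)
        g_hi = max(tr.span[1] for tr in group)
        lines.append(
            f"{chrom}\tmodscreen\tgene\t{g_lo}\t{g_hi}\t.\t{strand}\t.\tID={gene_id}"
        )
        for tr in group:
            lo, hi = tr.span
            lines.append(
                f"{tr.chromosome}\tmodscreen\tmRNA\t{lo}\t{hi}\t.\t{tr.strand}\t.\t"
                f"ID={tr.transcript_id};Parent={gene_id}"
            )
            for s, e in tr.exons:
                lines.append(
                    f"{tr.chromosome}\tmodscreen\texon\t{s}\t{e}\t.\t{tr.strand}\t.\t"
                    f"Parent={tr.transcript_id}"
                )
            c_lo, c_hi = tr.cds_span
            for s, e in tr.exons:
                cs, ce = max(s, c_lo), min(e, c_hi)
                if cs <= ce:
                    lines.append(
                        f"{tr.chromosome}\tmodscreen\tCDS\t{cs}\t{ce}\t.\t{tr.strand}\t0\t"
                        f"Parent={tr.transcript_id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfReadResult:
    """Substitution calls retained from one VCF plus skip/reject tallies."""

    calls: list[VariantCall]
    skipped_indels: int = 0
    rejected_missing_fields: int = 0


def _first_scalar(value):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _per_alt(value, index: int):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[index] if index < len(value) else None
    return value


def read_vcf(path: str | os.PathLike, strain_id: str | None = None) -> VcfReadResult:
    """Read substitution calls from a VCF v4.2 file.

    Depth and allele fraction come from DP and AF; the first sample's FORMAT
    values win over INFO when both are present. Multi-allelic records are
    split; indels are skipped and counted; records missing DP or AF are
    rejected and counted rather than aborting the read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    result = VcfReadResult(calls=[])
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        sid = strain_id if strain_id is not None else (samples[0] if samples else "")
        for rec in vcf:
            sample = rec.samples[samples[0]] if samples else None

            def fmt_or_info(key):
                if sample is not None and key in sample and sample[key] is not None:
                    v = sample[key]
                    if not (isinstance(v, (tuple, list)) and all(x is None for x in v)):
                        return v
                return rec.info.get(key)

            dp_raw = fmt_or_info("DP")
            af_raw = fmt_or_info("AF")
            for i, alt in enumerate(rec.alts or ()):
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref not in BASES or alt not in BASES:
                    result.skipped_indels += 1
                    continue
                dp = _first_scalar(dp_raw)
                af = _per_alt(af_raw, i)
                if dp is None or af is None:
                    result.rejected_missing_fields += 1
                    continue
                result.calls.append(
                    VariantCall(
                        strain_id=sid,
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref_base=rec.ref,
                        alt_base=alt,
                        read_depth=int(dp),
                        allele_fraction=round(float(af), AF_DECIMALS),
                    )
                )
    return result


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | os.PathLike,
    sample_id: str,
    contig_lengths: Mapping[str, int],
    extra_header_lines: Iterable[str] = (),
) -> None:
    """Write substitution calls as a single-sample VCF with DP/AF in FORMAT."""
    header = pysam.VariantHeader()
    for line in extra_header_lines:
        header.add_line(line)
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AF", "A", "Float", "Allele fraction of the alternate allele")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chromosome, c.position, c.alt_base)):
            rec = out.new_record(
                contig=call.chromosome,
                start=call.position - 1,
                stop=call.position,
                alleles=(call.ref_base, call.alt_base),
            )
            rec.samples[sample_id]["GT"] = (1, 1)
            rec.samples[sample_id]["DP"] = call.read_depth
            rec.samples[sample_id]["AF"] = round(call.allele_fraction, AF_DECIMALS)
            out.write(rec)


# ---------------------------------------------------------------------------
# Strain manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read the strain manifest TSV (strain_id, mutagen, vcf_path, role)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    bad_roles = set(df["role"]) - set(MANIFEST_ROLES)
    if bad_roles:
        raise FormatError(f"{path}: unknown manifest roles {sorted(bad_roles)}")
    bad_mut = set(df["mutagen"]) - set(MUTAGENS)
    if bad_mut:
        raise FormatError(f"{path}: unknown mutagens {sorted(bad_mut)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | os.PathLike,
                   header_comment: str | None = None) -> None:
    with open(path, "w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        df.to_csv(handle, sep="\t", index=False)
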