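"""Orchestration of the full analysis: simulate -> filter -> annotate ->
interpret -> phenotype summaries -> cost report.

Each stage is a plain function over a :class:`~modscreen.config.RunConfig`;
the CLI is a thin shell over these. All report files carry the seed and
config hash in a header line, and a fixed seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .annotation import EffectAnnotation, annotate, group_complex_alleles
from .config import RunConfig
from .errors import DataIntegrityError, ModscreenError
from .filtering import FilterResult, RetentionStatus, apply_filters
from .interpret import (
    RevertantStatus,
    recurrence_report,
    saturation_signals,
    validate_revertant,
)
from .io import read_fasta, read_gff3, read_manifest, read_vcf
from .phenotype import (
    METRICS,
    km_curve,
    population_events,
    read_hatch_tsv,
    read_population_tsv,
    strain_summary,
)
from . import cost as cost_model
from .simulate import emit_screen, simulate_screen

logger = logging.getLogger("modscreen")


def cmd_simulate(config: RunConfig) -> Path:
    """Emit a synthetic screen bundle under <outdir>/screen."""
    plan = config.screen_plan()  # validate before touching the filesystem
    spectra = {m: config.spectrum(m) for m in ("EMS", "ENU", "EMS+ENU")}
    outdir = Path(config.outdir) / "screen"
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_screen(plan, spectra=spectra, primary=config.primary_allele())
    emit_screen(bundle, outdir, header_comment=config.header_comment())
    logger.info("simulated %d strains into %s", plan.n_strains, outdir)
    return outdir


@dataclass
class StrainAnalysis:
    strain_id: str
    mutagen: str
    filter_result: FilterResult
    intragenic: list[EffectAnnotation]
    revertant_verdict: Optional[object]
    flag: str  # "", "REVERTED", "SUSPECTED_CONTAMINATION", ...


def analyze_strain(
    strain_id: str,
    mutagen: str,
    calls,
    parental_calls,
    transcripts,
    genome,
    config: RunConfig,
):
    """Filter one strain's calls and annotate its target-gene variants."""
    fconfig = config.filter_config()
    primary = config.primary_allele()
    result = apply_filters(calls, parental_calls, transcripts, fconfig, primary)
    by_chrom: dict[str, list] = {}
    for tr in transcripts:
        by_chrom.setdefault(tr.chromosome, []).append(tr)
    intragenic: list[EffectAnnotation] = []
    for call in result.passing:
        for tr in by_chrom.get(call.chromosome, ()):
            if tr.contains(call.chromosome, call.position) and tr.gene_id == primary.gene_id:
                intragenic.append(
                    annotate(tr, genome, call, fconfig.splice_window_nt)
                )
    verdict = None
    flag = ""
    if result.retention_status is RetentionStatus.REVERTED:
        rv = config.revertant
        verdict = validate_revertant(
            result,
            primary,
            config.spectrum(mutagen if mutagen in ("EMS", "ENU", "EMS+ENU") else "EMS+ENU"),
            min_load=rv.get("min_load", 20),
            min_fraction=rv.get("min_fraction", 0.9),
        )
        flag = verdict.status.value
    elif result.retention_status is RetentionStatus.NOT_OBSERVED:
        flag = "PRIMARY_NOT_OBSERVED"
    return StrainAnalysis(strain_id, mutagen, result, intragenic, verdict, flag)


def cmd_analyze(config: RunConfig) -> Path:
    """Run filter/annotate/interpret over every manifest strain.

    Writes a catalogue-style variants table (strain, mutagen, filtered-variant
    count, positions, ref/alt, effects), per-strain JSON summaries, and a
    recurrence/saturation report for the target gene.
    """
    paths = config.paths
    for key in ("genome", "gff3", "manifest"):
        if key not in paths:
            raise ModscreenError(f"config paths section missing {key!r}")
    outdir = Path(config.outdir) / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(paths["genome"])
    transcripts = read_gff3(paths["gff3"])
    manifest = read_manifest(paths["manifest"])
    base = Path(paths["manifest"]).parent

    parental_calls = []
    for row in manifest[manifest["role"] == "parental"].itertuples():
        parental_calls.extend(read_vcf(base / row.vcf_path, row.strain_id).calls)

    analyses: list[StrainAnalysis] = []
    for row in manifest[manifest["role"] != "parental"].itertuples():
        vcf_path = base / row.vcf_path
        if not vcf_path.exists():
            raise DataIntegrityError(
                f"strain {row.strain_id!r}: VCF not found at {vcf_path}"
            )
        read = read_vcf(vcf_path, row.strain_id)
        logger.info(
            "%s: %d calls (%d indels skipped, %d records missing DP/AF)",
            row.strain_id, len(read.calls), read.skipped_indels,
            read.rejected_missing_fields,
        )
        analyses.append(
            analyze_strain(
                row.strain_id, row.mutagen, read.calls, parental_calls,
                transcripts, genome, config,
            )
        )

    if not analyses:
        logger.warning("manifest lists no non-parental strains; reports are empty")
    header = config.header_comment()

    # catalogue-style table: one row per strain
    table_columns = [
        "strain", "mutagen", "n_filtered", "positions", "ref_alt",
        "variant_effects", "allele_label", "retention", "flag",
    ]
    rows = []
    for a in analyses:
        complexes = group_complex_alleles(a.intragenic)
        rows.append(
            {
                "strain": a.strain_id,
                "mutagen": a.mutagen,
                "n_filtered": a.filter_result.n_passing,
                "positions": ";".join(
                    f"{ann.variant.chromosome}:{ann.variant.position}"
                    for ann in a.intragenic
                ),
                "ref_alt": ";".join(
                    f"{ann.variant.ref_base}/{ann.variant.alt_base}"
                    for ann in a.intragenic
                ),
                "variant_effects": ";".join(
                    f"{ann.c_hgvs}" + (f" {ann.p_hgvs}" if ann.p_hgvs else "")
                    for ann in a.intragenic
                ),
                "allele_label": ";".join(complexes.values()),
                "retention": a.filter_result.retention_status.value,
                "flag": a.flag,
            }
        )
    with open(outdir / "variants_table.tsv", "w") as handle:
        handle.write(f"# {header}\n")
        pd.DataFrame(rows, columns=table_columns).to_csv(handle, sep="\t", index=False)

    # per-strain summaries
    summaries = {
        a.strain_id: {
            "mutagen": a.mutagen,
            "n_passing": a.filter_result.n_passing,
            "rejection_tally": a.filter_result.rejection_tally,
            "retention_status": a.filter_result.retention_status.value,
            "flag": a.flag,
            "revertant": (
                {
                    "status": a.revertant_verdict.status.value,
                    "background_load": a.revertant_verdict.background_load,
                    "spectrum_consistent_fraction": a.revertant_verdict.spectrum_consistent_fraction,
                }
                if a.revertant_verdict is not None
                else None
            ),
        }
        for a in analyses
    }
    _write_json(outdir / "strain_summaries.json", header, summaries)

    # recurrence and saturation over the target gene
    all_intragenic = [ann for a in analyses for ann in a.intragenic]
    prior_sites = _read_prior_sites(paths.get("prior_sites"))
    report = recurrence_report(all_intragenic, prior_sites)
    revertant_seen = any(
        a.revertant_verdict is not None
        and a.revertant_verdict.status is RevertantStatus.TRUE_REVERTANT
        for a in analyses
    )
    signals = saturation_signals(report, revertant_seen)
    _write_json(
        outdir / "interpretation.json",
        header,
        {
            "recurrence": {
                "multi_hit_positions": report.multi_hit_positions,
                "multi_hit_codons": report.multi_hit_codons,
                "prior_overlap": report.prior_overlap,
                "by_position": {
                    f"{c}:{p}:{r}>{al}": strains
                    for (c, p, r, al), strains in report.by_position.items()
                },
                "by_codon": {
                    f"{gene}:{idx}": hits for (gene, idx), hits in report.by_codon.items()
                },
            },
            "saturation": {
                "revertant_observed": signals.revertant_observed,
                "recurrent_position": signals.recurrent_position,
                "recurrent_codon": signals.recurrent_codon,
                "prior_overlap": signals.prior_overlap,
                "summary": signals.summary,
            },
        },
    )
    logger.info("analysis written to %s", outdir)
    return outdir


def cmd_phenotype(config: RunConfig) -> Path:
    """Summarise phenotype plates: catalogue-style strain table plus one
    product-limit curve per population metric and strain."""
    paths = config.paths
    for key in ("hatch", "population"):
        if key not in paths:
            raise ModscreenError(f"config paths section missing {key!r}")
    outdir = Path(config.outdir) / "phenotype"
    outdir.mkdir(parents=True, exist_ok=True)
    horizon = config.phenotype.get("horizon", 30)
    threshold = config.phenotype.get("threshold", 50)
    hatch = read_hatch_tsv(paths["hatch"])
    population = read_population_tsv(paths["population"], horizon=horizon)
    header = config.header_comment()

    summary = strain_summary(hatch, population, threshold=threshold)
    with open(outdir / "strain_summary.tsv", "w") as handle:
        handle.write(f"# {header}\n")
        summary.to_csv(handle, sep="\t", index=False)

    curve_rows = []
    strains = sorted({p.strain_id for p in population})
    for strain in strains:
        plates = [p for p in population if p.strain_id == strain]
        events = [population_events(p, threshold) for p in plates]
        for metric in METRICS:
            curve = km_curve([e[metric] for e in events])
            for t, s, d, c, r in zip(
                curve.event_times, curve.estimates, curve.n_events,
                curve.n_censored, curve.at_risk,
            ):
                curve_rows.append(
                    {
                        "strain": strain,
                        "metric": metric,
                        "day": t,
                        "at_risk": r,
                        "events": d,
                        "censored": c,
                        "survival": round(s, 6),
                        "reached_pct": round(100 * (1 - s), 2),
                    }
                )
    with open(outdir / "curves.tsv", "w") as handle:
        handle.write(f"# {header}\n")
        pd.DataFrame(curve_rows).to_csv(handle, sep="\t", index=False)
    logger.info("phenotype summaries written to %s", outdir)
    return outdir


def cmd_cost(config: RunConfig) -> Path:
    """Write the Sanger-vs-WGS comparison for the configured screen size."""
    outdir = Path(config.outdir) / "cost"
    outdir.mkdir(parents=True, exist_ok=True)
    n = config.cost.get("n_strains", cost_model.REFERENCE_N_STRAINS)
    sanger = cost_model.sanger_profile(n, **config.cost.get("sanger", {}))
    wgs = cost_model.wgs_profile(n, **config.cost.get("wgs", {}))
    comparison = cost_model.compare(sanger, wgs)
    header = config.header_comment()
    (outdir / "cost_report.txt").write_text(
        f"# {header}\n{comparison.render()}\n"
    )
    _write_json(
        outdir / "cost_report.json",
        header,
        {
            "n_strains": n,
            "sanger_total": str(comparison.sanger_total),
            "wgs_total": str(comparison.wgs_total),
            "sanger_per_strain": str(sanger.per_strain_cost),
            "wgs_per_strain": str(wgs.per_strain_cost),
            "sanger_hands_on_hours": str(sanger.hands_on_hours),
            "wgs_hands_on_hours": str(wgs.hands_on_hours),
        },
    )
    return outdir


def cmd_report(config: RunConfig) -> Path:
    """Run analyze + phenotype + cost against existing inputs."""
    cmd_analyze(config)
    cmd_phenotype(config)
    cmd_cost(config)
    return Path(config.outdir)


def _write_json(path: Path, header: str, payload) -> None:
    path.write_text(json.dumps({"_header": header, **payload}, indent=2) + "\n")


def _read_prior_sites(path: Optional[str]):
    if path is None:
        return None
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["position_key", "label"], dtype=str)
    sites = []
    for key in df["position_key"]:
        chrom, pos = key.split(":")
        sites.append((chrom, int(pos)))
    return sites
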