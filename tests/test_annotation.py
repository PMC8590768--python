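"""Coordinate arithmetic and codon-level effect annotation.

The deep checks are two independent oracles: a full-CDS re-translation diff
(Biopython) for random coding SNVs, and a mirror-image (reverse-complement)
construction for strand symmetry.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import make_transcript_on_genome
from modscreen import fixture as fx
from modscreen.annotation import (
    CdnaKind,
    EffectClass,
    annotate,
    burden_from_counts,
    burden_summary,
    cdna_to_genomic,
    codon_arithmetic,
    coding_sequence,
    genomic_to_cdna,
    group_complex_alleles,
)
from modscreen.errors import DataIntegrityError, DomainError
from modscreen.io import Genome, TranscriptModel, VariantCall, revcomp


class TestCodonArithmetic:
    @pytest.mark.parametrize(
        "cpos,expected",
        [
            (1, (1, 1)),
            (2, (1, 2)),
            (3, (1, 3)),
            (4, (2, 1)),
            (1154, (385, 2)),
            (1262, (421, 2)),
            (1325, (442, 2)),
            (1597, (533, 1)),
        ],
    )
    def test_examples(self, cpos, expected):
        assert codon_arithmetic(cpos) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            codon_arithmetic(0)

    def test_identity_over_range(self):
        for c in range(1, 3000):
            idx, off = codon_arithmetic(c)
            assert 1 <= off <= 3
            assert 3 * (idx - 1) + off == c


class TestCoordinateMapping:
    def test_fixture_pairs(self, fixture_transcript):
        for g, c in fx.COORDINATE_PAIRS:
            assert genomic_to_cdna(fixture_transcript, g).coding_position == c
            assert cdna_to_genomic(fixture_transcript, c) == g

    def test_off_span_is_domain_error(self, fixture_transcript):
        with pytest.raises(DomainError):
            genomic_to_cdna(fixture_transcript, 100)

    def test_utr3_kind(self, fixture_transcript):
        coord = genomic_to_cdna(fixture_transcript, 5_653_640)
        assert coord.kind is CdnaKind.UTR3

    def test_intron_anchors(self, fixture_transcript):
        # 83-nt intron between c.939 and c.940: 5,650,849..5,650,931
        coord = genomic_to_cdna(fixture_transcript, 5_650_849)
        assert coord.intron_anchor == (939, 1)
        coord = genomic_to_cdna(fixture_transcript, 5_650_931)
        assert coord.intron_anchor == (940, -1)
        coord = genomic_to_cdna(fixture_transcript, 5_650_849 + 2)
        assert coord.intron_anchor == (939, 3)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", [3, 7, 21])
    def test_roundtrip_on_random_transcripts(self, strand, seed):
        tr, _ = make_transcript_on_genome(seed, strand)
        spliced = tr.spliced_positions()
        for g in spliced:
            coord = genomic_to_cdna(tr, int(g))
            if coord.coding_position is not None:
                assert cdna_to_genomic(tr, coord.coding_position) == int(g)


def _retranslate_oracle(tr, genome, variant):
    """Expected (ref_aa, alt_aa, index) by translating the whole mutated CDS."""
    ref_cds = coding_sequence(tr, genome)
    mutated_genome = Genome(
        {
            tr.chromosome: (
                genome.sequences[tr.chromosome][: variant.position - 1]
                + variant.alt_base
                + genome.sequences[tr.chromosome][variant.position :]
            )
        }
    )
    alt_cds = coding_sequence(tr, mutated_genome)
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return None  # synonymous
    (i,) = diffs
    return ref_prot[i], alt_prot[i], i + 1


def _random_coding_snv(rng, tr, genome):
    spliced = tr.spliced_positions()
    lo, hi = tr.cds_span
    coding = [int(g) for g in spliced if lo <= g <= hi]
    pos = coding[int(rng.integers(0, len(coding)))]
    ref = genome.base(tr.chromosome, pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return VariantCall("S", tr.chromosome, pos, ref, alt, 30, 1.0)


class TestAnnotate:
    @pytest.mark.parametrize("v", fx.VARIANT_TABLE, ids=lambda v: v.c_hgvs)
    def test_designed_variant_catalogue(self, fixture_bundle, v):
        tr, genome = fixture_bundle
        call = VariantCall(v.strain_id, "II", v.position, v.ref_base, v.alt_base, 30, 1.0)
        ann = annotate(tr, genome, call)
        assert ann.c_hgvs == v.c_hgvs
        assert ann.p_hgvs == v.p_hgvs

    def test_ref_mismatch_names_strain_and_position(self, fixture_bundle):
        tr, genome = fixture_bundle
        wrong_ref = "G" if genome.base("II", 5_651_146) != "G" else "A"
        call = VariantCall("MT1", "II", 5_651_146, wrong_ref, "T", 30, 1.0)
        with pytest.raises(DataIntegrityError, match="MT1.*5651146"):
            annotate(tr, genome, call)

    def test_nonsense_and_synonymous_classes(self, fixture_bundle):
        tr, genome = fixture_bundle
        # codon 533 = AAA; c.1597 A>T makes TAA = stop
        call = VariantCall("S", "II", 5_653_611, "A", "T", 30, 1.0)
        ann = annotate(tr, genome, call)
        assert ann.effect_class is EffectClass.NONSENSE
        assert ann.p_hgvs == "p.K533*"
        # codon 409 = CAT; c.1227 T>C stays His
        call = VariantCall("S", "II", 5_651_219, "T", "C", 30, 1.0)
        assert annotate(tr, genome, call).effect_class is EffectClass.SYNONYMOUS

    def test_start_and_stop_loss(self, fixture_bundle):
        tr, genome = fixture_bundle
        g_start = fx.CDS_START_G  # A of ATG
        call = VariantCall("S", "II", g_start, "A", "G", 30, 1.0)
        ann = annotate(tr, genome, call)
        assert ann.effect_class is EffectClass.START_LOSS
        g_stop = cdna_to_genomic(tr, 1600)  # T of the TAA stop
        call = VariantCall("S", "II", g_stop, "T", "C", 30, 1.0)
        ann = annotate(tr, genome, call)
        assert ann.effect_class is EffectClass.STOP_LOSS
        assert ann.p_hgvs == "p.*534Q"

    def test_splice_prox_intronic_hgvs(self, fixture_bundle):
        tr, genome = fixture_bundle
        pos = 5_650_849 + 2  # 3 nt into the 83-nt intron
        ref = genome.base("II", pos)
        alt = "A" if ref != "A" else "G"
        ann = annotate(tr, genome, VariantCall("S", "II", pos, ref, alt, 30, 1.0))
        assert ann.effect_class is EffectClass.SPLICE_PROX
        assert ann.c_hgvs == f"c.939+3{ref}>{alt}"
        assert ann.p_hgvs == ""

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("seed", [5, 17])
    def test_codon_local_equals_full_retranslation(self, strand, seed):
        tr, genome = make_transcript_on_genome(seed, strand)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(250):
            variant = _random_coding_snv(rng, tr, genome)
            ann = annotate(tr, genome, variant)
            expected = _retranslate_oracle(tr, genome, variant)
            if expected is None:
                assert ann.effect_class is EffectClass.SYNONYMOUS
            else:
                ref_aa, alt_aa, idx = expected
                assert (ann.ref_aa, ann.alt_aa, ann.codon_index) == (ref_aa, alt_aa, idx)

    def test_strand_symmetry_via_mirror_genome(self):
        tr, genome = make_transcript_on_genome(42, "+")
        L = genome.length(tr.chromosome)
        mirror_genome = Genome({tr.chromosome: revcomp(genome.sequences[tr.chromosome])})
        mirror = TranscriptModel(
            gene_id=tr.gene_id,
            transcript_id=tr.transcript_id,
            chromosome=tr.chromosome,
            strand="-",
            exons=tuple(sorted((L - e + 1, L - s + 1) for s, e in tr.exons)),
            cds_start_g=L - tr.cds_start_g + 1,
            cds_end_g=L - tr.cds_end_g + 1,
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(7)
        for _ in range(100):
            v = _random_coding_snv(rng, tr, genome)
            mv = VariantCall(
                v.strain_id, v.chromosome, L - v.position + 1,
                comp[v.ref_base], comp[v.alt_base], v.read_depth, v.allele_fraction,
            )
            ann = annotate(tr, genome, v)
            mann = annotate(mirror, mirror_genome, mv)
            assert (ann.c_hgvs, ann.p_hgvs) == (mann.c_hgvs, mann.p_hgvs)


class TestComplexAllelesAndBurden:
    def _annotations(self, fixture_bundle, strain_id):
        tr, genome = fixture_bundle
        return [
            annotate(tr, genome, VariantCall(v.strain_id, "II", v.position, v.ref_base, v.alt_base, 30, 1.0))
            for v in fx.VARIANT_TABLE
            if v.strain_id == strain_id
        ]

    def test_two_variant_complex_allele(self, fixture_bundle):
        anns = self._annotations(fixture_bundle, "S02")
        assert group_complex_alleles(anns) == {"zyg-1": "P316H;S319A"}

    def test_sorted_by_codon_not_input_order(self, fixture_bundle):
        anns = self._annotations(fixture_bundle, "S06")
        assert group_complex_alleles(list(reversed(anns))) == {"zyg-1": "H409=;N420K"}

    def test_singleton_token(self, fixture_bundle):
        anns = self._annotations(fixture_bundle, "S01")
        assert group_complex_alleles(anns) == {"zyg-1": "A385V"}

    @pytest.mark.parametrize(
        "total,nonsense,splice,pct_nonsense,pct_splice",
        [
            (188, 5, 4, 2.66, 2.13),
            (70, 1, 2, 1.43, 2.86),
        ],
    )
    def test_burden_percentages_round_half_up(
        self, total, nonsense, splice, pct_nonsense, pct_splice
    ):
        summary = burden_from_counts(total, nonsense, splice)
        assert summary.pct_nonsense == pct_nonsense
        assert summary.pct_splice == pct_splice

    def test_empty_burden_is_undefined_not_zero_division(self):
        summary = burden_summary([])
        assert summary.n_total == 0
        assert summary.pct_nonsense is None and summary.pct_splice is None

    def test_burden_counts_from_annotations(self, fixture_bundle):
        tr, genome = fixture_bundle
        nonsense = annotate(tr, genome, VariantCall("S", "II", 5_653_611, "A", "T", 30, 1.0))
        pos = 5_650_849 + 2
        ref = genome.base("II", pos)
        alt = "A" if ref != "A" else "G"
        splice = annotate(tr, genome, VariantCall("S", "II", pos, ref, alt, 30, 1.0))
        missense = annotate(tr, genome, VariantCall("S", "II", 5_651_146, "C", "T", 30, 1.0))
        summary = burden_summary([nonsense, splice, missense])
        assert (summary.n_total, summary.n_nonsense, summary.n_splice) == (3, 1, 1)
        assert summary.pct_nonsense == 33.33
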