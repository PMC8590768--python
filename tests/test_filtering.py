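"""Region classification and the four-predicate homozygous-variant filter."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from modscreen.errors import ConfigError
from modscreen.filtering import (
    FilterConfig,
    RegionClass,
    RetentionStatus,
    apply_filters,
    classify_region,
)
from modscreen.fixture import fixture_primary_allele
from modscreen.io import PrimaryAllele, TranscriptModel, VariantCall

# the fixture's 83-nt intron runs 5,650,849..5,650,931
INTRON2_START = 5_650_849
INTRON2_END = 5_650_931


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (5_649_770, RegionClass.UTR5),          # c.-4
            (5_649_756, RegionClass.UTR5),          # c.-18
            (5_649_740, RegionClass.UTR5),          # deeper 5'UTR
            (5_650_846, RegionClass.CODING),        # c.937
            (5_653_611, RegionClass.CODING),        # c.1597
            (5_651_254, RegionClass.CODING),        # exon edge: CODING beats SPLICE_PROX
            (INTRON2_START + 2, RegionClass.SPLICE_PROX),   # 3 nt into the intron
            (INTRON2_START + 10, RegionClass.INTRONIC),     # 11 nt in
            (INTRON2_END - 2, RegionClass.SPLICE_PROX),     # acceptor side
            (5_652_000, RegionClass.INTRONIC),      # deep in the 2022-nt intron
            (5_653_640, RegionClass.UTR3),
            (5_653_700, RegionClass.INTERGENIC),    # past the last exon
            (100, RegionClass.INTERGENIC),
        ],
    )
    def test_fixture_positions(self, fixture_transcript, position, expected):
        assert classify_region([fixture_transcript], "II", position) == expected

    def test_other_chromosome_is_intergenic(self, fixture_transcript):
        assert classify_region([fixture_transcript], "X", 5_650_846) == RegionClass.INTERGENIC

    def test_window_zero_disables_splice_class(self, fixture_transcript):
        cls = classify_region([fixture_transcript], "II", INTRON2_START, splice_window_nt=0)
        assert cls == RegionClass.INTRONIC

    def test_minus_strand_utr_orientation(self):
        tr = TranscriptModel("g", "t", "I", "-", ((100, 220),), 200, 111)
        assert classify_region([tr], "I", 210) == RegionClass.UTR5
        assert classify_region([tr], "I", 105) == RegionClass.UTR3

    def test_priority_across_overlapping_transcripts(self, fixture_transcript):
        # a second transcript whose CDS covers a position intronic in the first
        other = TranscriptModel(
            "g2", "t2", "II", "+", ((5_651_900, 5_652_100),), 5_651_910, 5_652_050
        )
        pos = 5_652_000
        assert classify_region([fixture_transcript], "II", pos) == RegionClass.INTRONIC
        assert classify_region([fixture_transcript, other], "II", pos) == RegionClass.CODING


def _naive_filter(calls, parental, transcripts, config):
    """Independent brute-force evaluation of the four-predicate conjunction."""
    passing = []
    for c in calls:
        if not c.read_depth > config.min_depth_exclusive:
            continue
        if not c.allele_fraction > config.min_af_exclusive:
            continue
        region = classify_region(transcripts, c.chromosome, c.position, config.splice_window_nt)
        allowed = {RegionClass.CODING, RegionClass.SPLICE_PROX}
        if config.include_utr:
            allowed |= {RegionClass.UTR5, RegionClass.UTR3}
        if region not in allowed:
            continue
        if config.require_de_novo and any(
            (p.chromosome, p.position, p.ref_base, p.alt_base) == (c.chromosome, c.position, c.ref_base, c.alt_base)
            for p in parental
        ):
            continue
        passing.append(c)
    return passing


def _random_calls(rng, n, strain="S"):
    lo, hi = 5_649_000, 5_655_000
    calls = []
    for _ in range(n):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        calls.append(
            VariantCall(
                strain,
                "II",
                int(rng.integers(lo, hi)),
                str(ref),
                str(alt),
                int(rng.integers(0, 40)),
                round(float(rng.uniform(0.5, 1.0)), 4),
            )
        )
    return calls


class TestApplyFilters:
    def test_empty_call_list(self, fixture_transcript):
        result = apply_filters(
            [], [], [fixture_transcript], FilterConfig(), fixture_primary_allele()
        )
        assert result.passing == []
        assert all(v == 0 for v in result.rejection_tally.values())
        assert result.retention_status is RetentionStatus.REVERTED  # no call = wildtype site

    def test_toy_set_tallies_first_failed_criterion(self, fixture_transcript):
        primary = fixture_primary_allele()
        mk = lambda pos, depth, af, ref="C", alt="T": VariantCall("S", "II", pos, ref, alt, depth, af)
        parental_hit = mk(5_650_939, 30, 1.0, "C", "A")
        calls = [
            mk(5_651_146, 5, 1.0),          # depth 5: strict threshold fails
            mk(5_651_146, 30, 0.9),         # AF 0.9: strict threshold fails
            mk(5_652_000, 30, 1.0, "G", "A"),  # deep intron: region fails
            parental_hit,                    # matches parental: de novo fails
            mk(5_651_146, 6, 0.91),          # passes (depth 6 > 5, AF 0.91 > 0.9)
            mk(5_649_770, 30, 1.0, "T", "A"),  # 5'UTR passes by default
        ]
        result = apply_filters(
            calls, [parental_hit], [fixture_transcript], FilterConfig(), primary
        )
        assert result.rejection_tally == {
            "depth": 1, "allele_fraction": 1, "region": 1, "de_novo": 1,
        }
        assert [c.position for c in result.passing] == [5_651_146, 5_649_770]

    def test_tally_plus_passing_partitions_input(self, fixture_transcript):
        rng = np.random.default_rng(11)
        calls = _random_calls(rng, 200)
        result = apply_filters(
            calls, [], [fixture_transcript], FilterConfig(), fixture_primary_allele()
        )
        assert len(result.passing) + sum(result.rejection_tally.values()) == len(calls)

    def test_utr_excluded_in_strict_mode(self, fixture_transcript):
        call = VariantCall("S", "II", 5_649_770, "T", "A", 30, 1.0)
        strict = FilterConfig(include_utr=False)
        result = apply_filters(
            [call], [], [fixture_transcript], strict, fixture_primary_allele()
        )
        assert result.passing == []
        assert result.rejection_tally["region"] == 1

    def test_different_alt_at_parental_site_is_de_novo(self, fixture_transcript):
        parental = [VariantCall("P", "II", 5_651_146, "C", "T", 30, 1.0)]
        call = VariantCall("S", "II", 5_651_146, "C", "G", 30, 1.0)
        result = apply_filters(
            [call], parental, [fixture_transcript], FilterConfig(), fixture_primary_allele()
        )
        assert result.passing == [call]

    def test_empty_transcripts_is_config_error(self):
        with pytest.raises(ConfigError):
            apply_filters([], [], [], FilterConfig(), fixture_primary_allele())

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_call_sets(self, fixture_transcript, seed):
        rng = np.random.default_rng(seed)
        config = FilterConfig(
            min_depth_exclusive=int(rng.integers(0, 12)),
            min_af_exclusive=float(rng.uniform(0.5, 0.99)),
            splice_window_nt=int(rng.integers(0, 15)),
            include_utr=bool(rng.integers(0, 2)),
            require_de_novo=bool(rng.integers(0, 2)),
        )
        calls = _random_calls(rng, int(rng.integers(0, 100)))
        parental = _random_calls(rng, 10, strain="P") + calls[:3]
        result = apply_filters(
            calls, parental, [fixture_transcript], config, fixture_primary_allele()
        )
        assert result.passing == _naive_filter(calls, parental, [fixture_transcript], config)

    @given(
        depth_threshold=st.integers(0, 30),
        af_threshold=st.floats(0.0, 0.99),
        seed=st.integers(0, 100),
    )
    def test_raising_thresholds_never_grows_passing_set(
        self, fixture_transcript, depth_threshold, af_threshold, seed
    ):
        rng = np.random.default_rng(seed)
        calls = _random_calls(rng, 40)
        primary = fixture_primary_allele()
        base = apply_filters(
            calls, [], [fixture_transcript], FilterConfig(), primary
        )
        tighter = apply_filters(
            calls,
            [],
            [fixture_transcript],
            FilterConfig(
                min_depth_exclusive=max(5, depth_threshold),
                min_af_exclusive=max(0.9, af_threshold),
            ),
            primary,
        )
        assert set(c.key for c in tighter.passing) <= set(c.key for c in base.passing)


class TestRetention:
    def test_mutant_allele_present_is_retained(self, fixture_transcript):
        primary = fixture_primary_allele()
        call = VariantCall("S", "II", primary.position, "C", "T", 30, 1.0)
        result = apply_filters([call], [], [fixture_transcript], FilterConfig(), primary)
        assert result.retention_status is RetentionStatus.RETAINED

    def test_no_call_at_site_is_reverted(self, fixture_transcript):
        primary = fixture_primary_allele()
        call = VariantCall("S", "II", 5_651_146, "C", "T", 30, 1.0)
        result = apply_filters([call], [], [fixture_transcript], FilterConfig(), primary)
        assert result.retention_status is RetentionStatus.REVERTED

    def test_third_allele_at_site_is_not_observed(self, fixture_transcript):
        primary = fixture_primary_allele()
        call = VariantCall("S", "II", primary.position, "C", "G", 30, 1.0)
        result = apply_filters([call], [], [fixture_transcript], FilterConfig(), primary)
        assert result.retention_status is RetentionStatus.NOT_OBSERVED
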