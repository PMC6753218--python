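"""Frequency filtering, mosaic candidate window, and the ACMG combiner."""

import pytest
from hypothesis import given, settings, strategies as st

from epipanel.cohort import reference_findings
from epipanel.variants import (
    VariantRecord,
    classify_variants,
    combine_acmg_evidence,
    detect_mosaic_candidates,
    discrepancy_report,
    parse_evidence,
    population_frequency_filter,
    tabulate_inheritance,
)


def rec(**kw):
    base = dict(sample="S1", gene="G", variant="v")
    base.update(kw)
    return VariantRecord(**base)


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "model,freq,kept",
        [
            ("AD", 0.0, True),
            ("AD", None, True),        # novel variant: treated as zero frequency
            ("AD", 1e-6, False),       # any nonzero frequency fails the AD rule
            ("XL", 1e-6, False),       # X-linked follows the dominant rule
            ("AR", 5e-5, True),        # below 0.01%
            ("AR", 2e-4, False),       # above 0.01%
            ("AR", 1e-4, False),       # exactly 0.01% fails "lower than"
        ],
    )
    def test_rules(self, model, freq, kept):
        out = population_frequency_filter(
            [rec(inheritance_model=model, population_frequency=freq)]
        )
        assert (len(out) == 1) is kept

    def test_missing_model_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="epipanel"):
            out = population_frequency_filter([rec(inheritance_model=None)])
        assert out == []
        assert "inheritance model" in caplog.text

    @given(
        freq=st.floats(0, 0.5, allow_nan=False),
        lower=st.floats(0, 1, allow_nan=False),
        model=st.sampled_from(["AD", "AR", "XL"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_frequency(self, freq, lower, model):
        """Lowering a variant's frequency never removes a retained variant."""
        hi = rec(inheritance_model=model, population_frequency=freq)
        lo = rec(inheritance_model=model, population_frequency=freq * lower)
        if population_frequency_filter([hi]):
            assert population_frequency_filter([lo])


class TestMosaicWindow:
    def test_reference_mosaic_case_is_a_candidate(self):
        # deep panel genotype with ~6.4% VAF and strong read support
        out = detect_mosaic_candidates([rec(ref_depth=2427, alt_depth=167)])
        assert len(out) == 1
        assert out[0].vaf == pytest.approx(167 / 2594, abs=1e-6)

    @pytest.mark.parametrize(
        "ref,alt,accepted",
        [
            (270, 30, False),   # alt exactly 30: "above 30" is strict
            (279, 31, True),    # vaf 0.1, alt 31
            (150, 100, False),  # vaf 0.40: outside window
            (1900, 100, True),  # vaf 0.05 exactly: inclusive endpoint
            (300, 100, True),   # vaf 0.25 exactly: inclusive endpoint
            (1991, 9, False),   # below window and below count
        ],
    )
    def test_window_boundaries(self, ref, alt, accepted):
        out = detect_mosaic_candidates([rec(ref_depth=ref, alt_depth=alt)])
        assert (len(out) == 1) is accepted

    def test_zero_depth_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="epipanel"):
            assert detect_mosaic_candidates([rec()]) == []
        assert "zero depth" in caplog.text


class TestACMGCombiner:
    @pytest.mark.parametrize(
        "evidence,expected",
        [
            ("PVS1, PM2", "Likely Pathogenic"),
            ("PVS1, PS4, PM1", "Pathogenic"),
            ("PVS1, PM2, PP1", "Pathogenic"),        # PVS + 1 PM + 1 PP
            ("PS2, PS4, PM2", "Pathogenic"),         # two strong
            ("PS2, PM1, PM2, PP2, PP3", "Pathogenic"),
            ("PS4, PM2, PP1, PP2, PP3, PP4", "Pathogenic"),  # 1 PS + 1 PM + 4 PP
            ("PS2, PM2, PP2, PP3", "Likely Pathogenic"),
            ("PM1, PM2, PM5", "Likely Pathogenic"),  # three moderate
            ("PM2, PM5, PP1, PP2", "Likely Pathogenic"),
            ("PM2, PP2, PP3, PP4, PP5", "Likely Pathogenic"),
            ("PM2, PP2, PP3", "VUS"),
            ("", "VUS"),
            ("BA1", "Benign"),
            ("BS1, BS2", "Benign"),
            ("BS1, BP1", "Likely Benign"),
            ("BP1, BP4", "Likely Benign"),
            ("PVS1, PM2, BA1", "VUS"),               # conflicting evidence
        ],
    )
    def test_combining_rules(self, evidence, expected):
        assert combine_acmg_evidence(evidence) == expected

    def test_unknown_code_is_an_error_naming_the_code(self):
        with pytest.raises(ValueError, match="PX9"):
            combine_acmg_evidence("PVS1, PX9")

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValueError, match="PM2"):
            parse_evidence("PM2, PM2")

    def test_strength_modifier_counts_at_base_by_default(self):
        assert combine_acmg_evidence("PM2, PM6+, PP2, PP3") == "Likely Pathogenic"

    def test_strength_modifier_upgrade_switch(self):
        # upgraded PM6 acts as strong: 1 PS + 1 PM + 2 PP stays Likely Pathogenic
        assert combine_acmg_evidence(
            "PM2, PM6+, PP2, PP3", upgrade_modifiers=True
        ) == "Likely Pathogenic"
        # but PS-level PM6 with two further moderates reaches Pathogenic
        assert combine_acmg_evidence(
            "PM6+, PM1, PM2, PP2, PP3", upgrade_modifiers=True
        ) == "Pathogenic"


@pytest.fixture(scope="module")
def classified():
    df = reference_findings()
    records = [
        rec(
            sample=r["case"], gene=r["gene"], variant=r["variant"],
            inheritance=r["inheritance"], evidence=r["evidence"],
            asserted_classification=r["classification"],
        )
        for _, r in df.iterrows()
    ]
    return classify_variants(records)


class TestReferenceTable:
    """The packaged findings table against the combiner and the tallies."""

    def test_combiner_reproduces_most_published_labels(self, classified):
        concordant = [c for c in classified if not c.discrepant]
        assert len(classified) == 48
        assert len(concordant) == 45

    def test_discrepancies_are_reported_not_silently_accepted(self, classified):
        report = discrepancy_report(classified)
        for case in ("Case 85", "Case 64", "Case 100"):
            assert case in report
        assert report.count("\n") == 4  # header + exactly three rows

    def test_inheritance_tabulation(self, classified):
        counts = tabulate_inheritance(classified)
        assert counts["de novo"] == 17
        assert counts["from asymptomatic parent"] == 6
        assert counts["from symptomatic parent"] == 8
        assert counts["from mosaic carrier parent"] == 2
        assert sum(counts.values()) == 48

    def test_empty_input_gives_all_zero_counts(self):
        counts = tabulate_inheritance([])
        assert set(counts.values()) == {0}
        assert "de novo" in counts


class TestVCFRoundTrip:
    def test_variant_records_survive_vcf_round_trip(self, tmp_path):
        pytest.importorskip("pysam")
        pytest.importorskip("cyvcf2")
        from epipanel.synthetic import variants_to_vcf
        from epipanel.variants import variants_from_vcf

        records = [
            rec(sample="S1", gene="GENEX", population_frequency=0.01,
                ref_depth=100, alt_depth=50, inheritance_model="AD"),
            rec(sample="S2", gene="GENEY", ref_depth=800, alt_depth=60),
        ]
        path = tmp_path / "variants.vcf"
        variants_to_vcf(records, path)
        back = variants_from_vcf(path, {"GENEX": "AD", "GENEY": "AD"})
        assert len(back) == 2
        by_sample = {v.sample: v for v in back}
        assert by_sample["S1"].alt_depth == 50
        assert by_sample["S1"].population_frequency == pytest.approx(0.01, rel=1e-4)
        assert by_sample["S2"].ref_depth == 800
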