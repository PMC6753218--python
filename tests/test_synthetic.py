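"""Ground-truthed generators: determinism, conservation, analytic expectations."""

import numpy as np
import pytest

from epipanel.depth import PanelConfigError
from epipanel.synthetic import (
    CNVSpike,
    MosaicSpike,
    SimulationConfig,
    simulate_amplicon_readset,
    simulate_cohort,
    simulate_coverage_matrix,
    simulate_panel_design,
    simulate_variant_table,
)


class TestPanelDesign:
    def test_first_kit_scale(self):
        design = simulate_panel_design(SimulationConfig(seed=3, n_genes=79))
        assert len(design.genes) == 79
        counts = design.exons_per_gene()
        assert all(5 <= n <= 30 for n in counts.values())

    def test_minimal_single_exon_design(self):
        cfg = SimulationConfig(seed=3, n_genes=1, exons_per_gene=(1, 1))
        design = simulate_panel_design(cfg)
        assert len(design) == 1
        assert design.exons[0].gene == "GENE001"

    def test_exons_sorted_and_non_overlapping(self):
        design = simulate_panel_design(SimulationConfig(seed=8, n_genes=20))
        prev_end = -1
        for e in design.exons:
            assert e.start >= prev_end
            assert e.end > e.start
            prev_end = e.end

    def test_deterministic_under_fixed_seed(self):
        a = simulate_panel_design(SimulationConfig(seed=5))
        b = simulate_panel_design(SimulationConfig(seed=5))
        assert a.exons == b.exons

    def test_invalid_ranges_rejected(self):
        with pytest.raises(PanelConfigError):
            SimulationConfig(exons_per_gene=(0, 5))
        with pytest.raises(PanelConfigError):
            SimulationConfig(exon_length=(300, 100))


class TestCoverageMatrix:
    def test_spiked_deletion_halves_mean_depth(self):
        """Dosage 0.5 on one gene: mean count ratio ~0.5 over replicate draws."""
        cfg0 = SimulationConfig(seed=1, n_samples=4, n_genes=5,
                                sample_depth_sd=0.0, exon_bias_sd=0.0)
        design = simulate_panel_design(cfg0)
        gene = design.genes[0]
        rows = [k for k, e in zip(design.keys, design.exons) if e.gene == gene]
        ratios = []
        for rep in range(100):
            cfg = SimulationConfig(
                seed=100 + rep, n_samples=4, n_genes=5,
                sample_depth_sd=0.0, exon_bias_sd=0.0,
                cnv_spikes=[CNVSpike("S001", gene, "deletion", 0.5)],
            )
            dm, truth = simulate_coverage_matrix(design, cfg)
            assert truth.cnv_spikes == cfg.cnv_spikes
            spiked = dm.counts.loc[rows, "S001"].mean()
            others = dm.counts.loc[rows, ["S002", "S003", "S004"]].to_numpy().mean()
            ratios.append(spiked / others)
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.01)

    def test_zero_noise_degenerate_case(self):
        cfg = SimulationConfig(seed=1, n_samples=3, n_genes=2,
                               sample_depth_sd=0.0, exon_bias_sd=0.0,
                               poisson_noise=False)
        design = simulate_panel_design(cfg)
        dm, _ = simulate_coverage_matrix(design, cfg)
        arr = dm.counts.to_numpy()
        assert (arr == arr[:, [0]]).all()  # all samples identical

    def test_mean_depth_scale_without_spikes(self):
        """Per-exon cohort mean count matches the analytic expectation."""
        cfg = SimulationConfig(seed=2, n_samples=30, n_genes=10,
                               sample_depth_sd=0.0, exon_bias_sd=0.0,
                               mean_depth=1000.0)
        design = simulate_panel_design(cfg)
        dm, _ = simulate_coverage_matrix(design, cfg)
        expected = 1000.0 * design.lengths().to_numpy() / cfg.read_length
        observed = dm.counts.mean(axis=1).to_numpy()
        se = np.sqrt(expected / cfg.n_samples)
        assert (np.abs(observed - expected) <= 3.5 * se).all()

    def test_deterministic_under_fixed_seed(self):
        cfg = SimulationConfig(seed=4, n_samples=3, n_genes=3)
        design = simulate_panel_design(cfg)
        a, _ = simulate_coverage_matrix(design, cfg)
        b, _ = simulate_coverage_matrix(design, cfg)
        assert a.counts.equals(b.counts)

    def test_spike_referencing_unknown_entities_rejected(self):
        cfg = SimulationConfig(seed=1, n_samples=2, n_genes=2)
        design = simulate_panel_design(cfg)
        bad_gene = SimulationConfig(
            seed=1, n_samples=2, n_genes=2,
            cnv_spikes=[CNVSpike("S001", "NOPE", "deletion", 0.5)],
        )
        with pytest.raises(PanelConfigError, match="NOPE"):
            simulate_coverage_matrix(design, bad_gene)
        bad_sample = SimulationConfig(
            seed=1, n_samples=2, n_genes=2,
            cnv_spikes=[CNVSpike("S999", design.genes[0], "deletion", 0.5)],
        )
        with pytest.raises(PanelConfigError, match="S999"):
            simulate_coverage_matrix(design, bad_sample)

    def test_dosage_ratio_validation(self):
        with pytest.raises(PanelConfigError):
            CNVSpike("S1", "G", "deletion", 2.5)
        with pytest.raises(PanelConfigError):
            CNVSpike("S1", "G", "duplication", 0.5)


class TestAmpliconReadset:
    def test_zero_vaf_zero_error_gives_no_alt_reads(self):
        reads, truth = simulate_amplicon_readset(
            {"S1": "AACCGG"}, {"S1": 0.0}, n_reads=500, error_rate=0.0, seed=1,
        )
        assert truth.amplicon_truth["S1"]["n_alt_templates"] == 0
        site = truth.amplicon_truth["_site"]
        assert all(r[10 + site["offset"]] == site["ref"] for r in reads)

    def test_half_vaf_within_binomial_error(self):
        _, truth = simulate_amplicon_readset(
            {"S1": "AACCGG"}, {"S1": 0.5}, n_reads=10_000, error_rate=0.0, seed=3,
        )
        frac = truth.amplicon_truth["S1"]["n_alt_templates"] / 10_000
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_read_conservation_across_samples(self):
        reads, _ = simulate_amplicon_readset(
            {"S1": "AACCGG", "S2": "TTGGCC"}, {}, n_reads=750, error_rate=0.01, seed=4,
        )
        assert len(reads) == 1500
        assert all(len(r) == 10 + 80 for r in reads)

    def test_deterministic_under_fixed_seed(self):
        a, _ = simulate_amplicon_readset({"S1": "AACCGG"}, {"S1": 0.3}, 200, 0.01, 7)
        b, _ = simulate_amplicon_readset({"S1": "AACCGG"}, {"S1": 0.3}, 200, 0.01, 7)
        assert a == b


class TestCohortSimulation:
    def test_exact_group_sizes_and_rounded_diagnosed_counts(self):
        cases, truth = simulate_cohort(
            {"neonatal": 26}, {"neonatal": 16 / 26}, seed=1
        )
        assert len(cases) == 26
        assert sum(c.diagnosed for c in cases) == 16
        assert sum(truth.diagnoses.values()) == 16
        assert all(c.onset_group == "neonatal" for c in cases)

    def test_zero_yield_means_no_diagnoses(self):
        cases, _ = simulate_cohort({"neonatal": 10}, {"neonatal": 0.0}, seed=2)
        assert sum(c.diagnosed for c in cases) == 0

    def test_printed_group_sizes_total(self):
        cases, _ = simulate_cohort(
            {"neonatal": 26, "early infantile": 58, "late infantile": 28},
            {"neonatal": 16 / 26, "early infantile": 29 / 58, "late infantile": 8 / 28},
            seed=3,
        )
        assert len(cases) == 112

    def test_negative_size_rejected(self):
        with pytest.raises(PanelConfigError):
            simulate_cohort({"neonatal": -1}, {}, seed=1)


class TestVariantTable:
    def test_class_mix_counts_and_properties(self):
        records, truth = simulate_variant_table(
            100, {"common": 0.3, "rare-AD": 0.3, "rare-AR": 0.2, "mosaic": 0.2},
            seed=6,
        )
        assert len(records) == 100
        classes = [t["class"] for t in truth.mosaic_truth]
        assert classes.count("common") == 30
        assert classes.count("mosaic") == 20
        by_name = {r.variant: r for r in records}
        for t in truth.mosaic_truth:
            r = by_name[t["variant"]]
            if t["class"] == "common":
                assert r.population_frequency > 0
            if t["class"] == "mosaic":
                assert r.total_depth >= 500
                assert 0.05 <= t["true_vaf"] <= 0.25

    def test_mosaic_spike_alt_count_matches_expectation(self):
        """VAF 0.064 at depth 2,594 gives ~167 variant reads."""
        spike = MosaicSpike("S001", "siteX", 167 / 2594, 2594)
        draws = []
        for seed in range(100):
            records, _ = simulate_variant_table(
                0, {"mosaic": 1.0}, seed=seed, mosaic_spikes=[spike]
            )
            draws.append(records[0].alt_depth)
        se = np.sqrt(2594 * spike.vaf * (1 - spike.vaf))
        assert abs(np.mean(draws) - 167) <= 3 * se / np.sqrt(100)

    def test_bad_mix_rejected(self):
        with pytest.raises(PanelConfigError, match="sum"):
            simulate_variant_table(10, {"common": 0.5}, seed=1)

    def test_deterministic_under_fixed_seed(self):
        mix = {"common": 0.5, "rare-AD": 0.25, "rare-AR": 0.15, "mosaic": 0.1}
        a, _ = simulate_variant_table(40, mix, seed=11)
        b, _ = simulate_variant_table(40, mix, seed=11)
        assert a == b


def test_all_common_mix_is_fully_removed_by_frequency_filter():
    from epipanel.variants import population_frequency_filter

    records, _ = simulate_variant_table(
        30, {"common": 1.0, "rare-AD": 0, "rare-AR": 0, "mosaic": 0}, seed=9
    )
    ad_records = [r for r in records if r.inheritance_model == "AD"]
    assert population_frequency_filter(ad_records) == []
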