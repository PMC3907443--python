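"""The synthetic generator: genomes, planted sites, tags, genes, Cq tables."""

import numpy as np
import pytest

from stat5kit.synthetic import (
    CqTable,
    GenePlacement,
    RegulationTruth,
    SiteTruth,
    generate_gene_annotation,
    generate_genome,
    plant_sites,
    simulate_qpcr,
    simulate_tags,
)
from stat5kit.core_io import GenomicInterval


class TestGenerateGenome:
    def test_length_alphabet_and_determinism(self):
        g1 = generate_genome(10_000, seed=1)
        g2 = generate_genome(10_000, seed=1)
        (seq,) = g1.values()
        assert len(seq) == 10_000
        assert set(seq) <= set("ACGT")
        assert g1 == g2
        assert g1 != generate_genome(10_000, seed=2)

    def test_gc_fraction_approximate(self):
        (seq,) = generate_genome(200_000, gc=0.41, seed=3).values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.41, abs=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(500)
        with pytest.raises(ValueError):
            generate_genome(10_000, gc=1.5)


@pytest.fixture(scope="module")
def planted():
    genome = generate_genome(2_000_000, seed=5)
    return plant_sites(
        genome, {"equal": 4, "A-dom": 2, "B-dom": 2, "A-sp": 2, "B-sp": 2}, seed=6
    )


class TestPlantSites:

    def test_class_counts_and_total(self, planted):
        _, sites = planted
        by_class = {}
        for s in sites:
            by_class[s.truth_class] = by_class.get(s.truth_class, 0) + 1
        assert by_class == {"equal": 4, "A-dom": 2, "B-dom": 2, "A-sp": 2, "B-sp": 2}

    def test_motifs_written_into_genome(self, planted):
        genome, sites = planted
        (seq,) = genome.values()
        for s in sites:
            assert seq[s.interval.start : s.interval.end] == s.motif
            assert s.motif.startswith("TTC") and s.motif.endswith("GAA")

    def test_minimum_gap_and_edge_margin(self, planted):
        _, sites = planted
        starts = sorted(s.interval.start for s in sites)
        assert min(np.diff(starts)) >= 5_000
        assert starts[0] >= 20_000
        (length,) = (2_000_000,)
        assert max(s.interval.end for s in sites) <= length - 20_000

    def test_lambda_regime_contracts(self, planted):
        _, sites = planted
        for s in sites:
            if s.truth_class == "equal":
                ratio = max(s.lambda_a, s.lambda_b) / min(s.lambda_a, s.lambda_b)
                assert ratio <= 1.5
            elif s.truth_class in ("A-dom", "B-dom"):
                hi, lo = max(s.lambda_a, s.lambda_b), min(s.lambda_a, s.lambda_b)
                assert lo > 0 and 4.0 <= hi / lo <= 5.0
                major = "A" if s.lambda_a > s.lambda_b else "B"
                assert s.truth_class == f"{major}-dom"
            else:
                minor = s.lambda_b if s.truth_class == "A-sp" else s.lambda_a
                assert minor == 0.0

    def test_deterministic_given_seed(self):
        genome = generate_genome(500_000, seed=7)
        a = plant_sites(genome, {"equal": 3}, seed=8)
        b = plant_sites(genome, {"equal": 3}, seed=8)
        assert a == b

    def test_overfull_genome_rejected(self):
        genome = generate_genome(50_000, seed=9)
        with pytest.raises(ValueError, match="too short"):
            plant_sites(genome, {"equal": 10}, min_gap=5_000)

    def test_unknown_class_and_small_gap_rejected(self):
        genome = generate_genome(100_000, seed=9)
        with pytest.raises(ValueError):
            plant_sites(genome, {"weird": 1})
        with pytest.raises(ValueError):
            plant_sites(genome, {"equal": 1}, min_gap=100)


class TestSimulateTags:
    @staticmethod
    def sites():
        return [
            SiteTruth(GenomicInterval("chr1", 100_000, 100_009), "TTCAAAGAA", 500.0, 100.0, "A-dom"),
        ]

    def test_input_control_is_background_only(self):
        tags = simulate_tags(self.sites(), "input", {"chr1": 1_000_000},
                             background_rate=0.001, seed=10)
        window = GenomicInterval("chr1", 99_500, 100_500)
        # ~1 background tag expected in the window; site lambda ignored
        assert tags.count_in(window) < 20
        assert tags.total_count == pytest.approx(1000, rel=0.2)

    def test_factor_tags_concentrate_at_site(self):
        tags = simulate_tags(self.sites(), "A", {"chr1": 1_000_000},
                             background_rate=0.0, seed=11)
        assert tags.total_count == pytest.approx(500, rel=0.2)
        window = GenomicInterval("chr1", 99_500, 100_500)  # ±~6.7 frag sigmas
        assert tags.count_in(window) == tags.total_count

    def test_minor_factor_uses_its_own_lambda(self):
        tags = simulate_tags(self.sites(), "B", {"chr1": 1_000_000},
                             background_rate=0.0, seed=12)
        assert tags.total_count == pytest.approx(100, rel=0.4)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate_tags([], "C", {"chr1": 1_000_000})
        with pytest.raises(ValueError):
            simulate_tags([], "A", {"chr1": 1_000_000}, frag_sigma=0)
        with pytest.raises(ValueError):
            simulate_tags([], "A", {"chr1": 1_000_000}, background_rate=-1)


class TestGeneAnnotation:
    @staticmethod
    def site(start=100_000):
        return SiteTruth(
            GenomicInterval("chr1", start, start + 9), "TTCAAAGAA", 100.0, 100.0, "equal"
        )

    def test_near_gene_within_window(self):
        genes = generate_gene_annotation(
            [self.site()], [GenePlacement("g", 0, mode="near", offset=4_000)],
            {"chr1": 1_000_000},
        )
        (g,) = genes
        assert self.site().interval.distance_to(g.interval) == 4_000

    def test_far_gene_beyond_window(self):
        genes = generate_gene_annotation(
            [self.site()], [GenePlacement("g", 0, mode="far", offset=15_000)],
            {"chr1": 1_000_000},
        )
        assert self.site().interval.distance_to(genes[0].interval) == 15_000

    def test_paired_near_plants_flanking_partner(self):
        genes = generate_gene_annotation(
            [self.site()],
            [GenePlacement("g", 0, mode="paired-near", offset=2_000, side=+1)],
            {"chr1": 1_000_000},
        )
        ids = {g.gene_id for g in genes}
        assert ids == {"g", "g_pair"}
        site = self.site()
        left = next(g for g in genes if g.interval.end <= site.interval.start)
        right = next(g for g in genes if g.interval.start >= site.interval.end)
        assert site.interval.distance_to(left.interval) == 2_000
        assert site.interval.distance_to(right.interval) == 2_000

    def test_contradictory_offsets_rejected(self):
        with pytest.raises(ValueError):
            generate_gene_annotation(
                [self.site()], [GenePlacement("g", 0, mode="far", offset=5_000)],
                {"chr1": 1_000_000},
            )
        with pytest.raises(ValueError):
            generate_gene_annotation(
                [self.site()], [GenePlacement("g", 0, mode="near", offset=50_000)],
                {"chr1": 1_000_000},
            )

    def test_off_chromosome_placement_rejected(self):
        with pytest.raises(ValueError, match="off chromosome"):
            generate_gene_annotation(
                [self.site(start=1_000)],
                [GenePlacement("g", 0, mode="near", offset=5_000, side=-1)],
                {"chr1": 1_000_000},
            )


class TestSimulateQpcr:
    def test_table_structure(self):
        truths = [RegulationTruth("g1", "B-specific", 0.0, 0.5)]
        cq = simulate_qpcr(truths, n_donors=4, seed=13)
        assert cq.genes == ["g1"]
        assert len(cq.donors) == 4
        assert len(cq.df) == 4 * 3  # donors × conditions

    def test_effect_recovered_from_ddcq_at_low_noise(self):
        truths = [RegulationTruth("g1", "B-specific", 0.0, 0.5)]
        cq = simulate_qpcr(truths, n_donors=50, sd_noise=0.01, seed=14)
        from stat5kit.qpcr import relative_expression

        ratios_b = relative_expression(cq, "g1", "B-KD")
        ratios_a = relative_expression(cq, "g1", "A-KD")
        assert ratios_b.mean() == pytest.approx(0.5, abs=0.02)
        assert ratios_a.mean() == pytest.approx(1.0, abs=0.02)

    def test_full_knockdown_and_small_panels_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr([RegulationTruth("g", "none", 0.0, 0.0)], n_donors=2)
        with pytest.raises(ValueError, match="infinite"):
            simulate_qpcr([RegulationTruth("g", "A-specific", 1.0, 0.0)])

    def test_cq_table_round_trip(self, tmp_path):
        cq = simulate_qpcr([RegulationTruth("g1", "none", 0.0, 0.0)], seed=15)
        path = tmp_path / "cq.tsv"
        cq.to_tsv(path)
        back = CqTable.from_tsv(path)
        assert back.genes == cq.genes and back.donors == cq.donors

    def test_cq_table_validation(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "donor": ["d1", "d1"],
                "gene": ["g", "g"],
                "condition": ["ctrl-siRNA", "A-KD"],
                "cq_target": [24.0, 25.0],
                "cq_reference": [20.0, 20.0],
            }
        )
        with pytest.raises(ValueError, match="three conditions"):
            CqTable(df)
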