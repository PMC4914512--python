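import numpy as np
import pandas as pd
import pytest

from magscope import bin_qc_refine as qc
from magscope import synthetic_community as syn
from magscope.errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidPolygonError,
    MissingDataError,
)

from oracles import (
    modified_zscore_oracle,
    per_base_mean_depth_oracle,
    triangle_contains_oracle,
)

UNIT_SQUARE = qc.PolygonSelection(((0, 0), (1, 0), (1, 1), (0, 1)))


class TestPolygonSelection:
    def test_needs_three_vertices(self):
        with pytest.raises(InvalidPolygonError):
            qc.PolygonSelection(((0, 0), (1, 1)))

    def test_self_intersecting_rejected(self):
        with pytest.raises(InvalidPolygonError):
            qc.PolygonSelection(((0, 0), (1, 1), (1, 0), (0, 1)))  # bow-tie

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidPolygonError):
            qc.PolygonSelection(((0, 0), (1, 1), (2, 2)))


class TestPointsInPolygon:
    def test_interior_point(self):
        assert qc.point_in_polygon(0.5, 0.5, UNIT_SQUARE)

    def test_exterior_point(self):
        assert not qc.point_in_polygon(2.0, 2.0, UNIT_SQUARE)

    def test_boundary_included(self):
        assert qc.point_in_polygon(0.0, 0.5, UNIT_SQUARE)
        assert qc.point_in_polygon(1.0, 1.0, UNIT_SQUARE)
        assert qc.point_in_polygon(0.5, 0.0, UNIT_SQUARE)

    def test_matches_triangle_oracle_on_random_points(self, rng):
        tri = ((0.1, 0.2), (0.9, 0.3), (0.4, 0.95))
        polygon = qc.PolygonSelection(tri)
        pts = rng.uniform(-0.2, 1.2, size=(1_000, 2))
        for x, y in pts:
            assert qc.point_in_polygon(x, y, polygon) == \
                triangle_contains_oracle(x, y, tri)

    def test_frame_interface(self):
        points = pd.DataFrame({"chunk_id": ["a", "b"], "x": [0.5, 3.0],
                               "y": [0.5, 3.0]})
        assert qc.points_in_polygon(points, UNIT_SQUARE) == ["a"]


class TestChunksToContigs:
    CHUNK_MAP = pd.DataFrame({
        "parent_contig": ["c1"] * 4 + ["c2"] * 4,
        "start": [0, 5_000, 10_000, 15_000] * 2,
        "end": [5_000, 10_000, 15_000, 20_000] * 2,
        "chunk_id": [f"c1|{i}" for i in range(4)] + [f"c2|{i}" for i in range(4)],
    })

    def test_majority_includes_three_of_four(self):
        sel = ["c1|0", "c1|1", "c1|2"]
        assert qc.chunks_to_contigs(sel, self.CHUNK_MAP) == ["c1"]

    def test_majority_excludes_one_of_four_but_any_includes(self):
        sel = ["c1|0"]
        assert qc.chunks_to_contigs(sel, self.CHUNK_MAP) == []
        assert qc.chunks_to_contigs(sel, self.CHUNK_MAP, rule="any") == ["c1"]

    def test_exact_tie_excluded_under_majority(self):
        sel = ["c1|0", "c1|1"]
        assert qc.chunks_to_contigs(sel, self.CHUNK_MAP) == []

    def test_unknown_rule(self):
        with pytest.raises(InvalidParameterError):
            qc.chunks_to_contigs([], self.CHUNK_MAP, rule="bogus")

    def test_unknown_chunk_fatal(self):
        with pytest.raises(MissingDataError):
            qc.chunks_to_contigs(["ghost"], self.CHUNK_MAP)


class TestCompletenessContamination:
    def make_hits(self, mapping):
        return pd.DataFrame(list(mapping), columns=["gene_id", "family_id"])

    def test_single_complete_genome(self):
        hits = self.make_hits((f"g{i}", f"fam{i:03d}") for i in range(107))
        g2c = {f"g{i}": "c1" for i in range(107)}
        report = qc.completeness_contamination(["c1"], hits, g2c)
        assert (report.n_families_present, report.n_families_multicopy) == (107, 0)

    def test_merged_genomes_fully_contaminated(self):
        rows = [(f"a{i}", f"fam{i:03d}") for i in range(107)]
        rows += [(f"b{i}", f"fam{i:03d}") for i in range(107)]
        hits = self.make_hits(rows)
        g2c = {f"a{i}": "cA" for i in range(107)}
        g2c.update({f"b{i}": "cB" for i in range(107)})
        report = qc.completeness_contamination(["cA", "cB"], hits, g2c)
        assert (report.n_families_present, report.n_families_multicopy) == (107, 107)

    def test_planted_contamination_counted(self):
        spec_genes = {f"g{i}": f"gen{'A' if i < 150 else 'B'}" for i in range(300)}
        truth = syn.GroundTruth(gene_to_genome=spec_genes)
        hits = syn.plant_marker_families(truth, n_families=107,
                                         contamination_copies=5, seed=0)
        g2c = {g: f"c_{spec_genes[g]}" for g in spec_genes}
        report = qc.completeness_contamination(["c_genA"], hits, g2c)
        assert report.n_families_present == 107
        assert report.n_families_multicopy == 5

    def test_genes_off_bin_ignored(self):
        hits = self.make_hits([("g1", "fam000"), ("g2", "fam001")])
        report = qc.completeness_contamination(["c1"], hits,
                                               {"g1": "c1", "g2": "elsewhere"})
        assert report.n_families_present == 1


class TestGcPerSequence:
    def test_half_gc(self):
        assert qc.gc_per_sequence({"s": "ATGC"})["s"] == pytest.approx(50.0)

    def test_all_gc(self):
        assert qc.gc_per_sequence({"s": "GGCC"})["s"] == pytest.approx(100.0)

    def test_ambiguous_excluded_from_denominator(self):
        assert qc.gc_per_sequence({"s": "ANT"})["s"] == pytest.approx(0.0)

    def test_no_unambiguous_bases_is_nan(self):
        assert np.isnan(qc.gc_per_sequence({"s": "NNN"})["s"])


class TestGcDistributionCompare:
    def test_identical_samples_zero_distance(self, rng):
        v = rng.uniform(30, 60, size=50)
        out = qc.gc_distribution_compare(v, v)
        assert out["emd"] == pytest.approx(0.0)
        assert out["median_a"] == out["median_b"]

    def test_pure_shift_closed_form(self, rng):
        v = rng.uniform(30, 60, size=100)
        out = qc.gc_distribution_compare(v, v + 10)
        assert out["emd"] == pytest.approx(10.0, abs=1e-9)

    def test_mixture_has_larger_iqr(self, rng):
        a = rng.normal(30, 1.5, size=200)
        b = rng.normal(65, 1.5, size=200)
        mixed = np.concatenate([a, b])
        out = qc.gc_distribution_compare(a, mixed)
        assert out["iqr_b"] > out["iqr_a"]

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            qc.gc_distribution_compare([1, 2, 3], [1, 2, 3, 4, 5])


class TestModifiedZscore:
    def test_hand_computed_1_to_9(self):
        scores = qc.modified_zscore(np.arange(1.0, 10.0))
        assert scores[-1] == pytest.approx(0.6745 * 4 / 2, abs=1e-12)

    def test_mad_zero_fallback(self):
        scores = qc.modified_zscore([10.0, 10, 10, 10, 100])
        # MeanAD = 18 -> score of 100 is 90 / (1.253314 * 18) = 3.9894
        assert scores[-1] == pytest.approx(90 / (1.253314 * 18), abs=1e-12)
        assert abs(scores[-1]) > 3.5

    def test_constant_vector_all_zero(self):
        np.testing.assert_array_equal(qc.modified_zscore([5.0, 5, 5, 5]), 0.0)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            qc.modified_zscore([1.0, 2.0])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(50, 10, size=int(rng.integers(3, 40)))
            np.testing.assert_allclose(
                qc.modified_zscore(x), modified_zscore_oracle(x), atol=1e-12)


class TestCoverageOutlierFilter:
    def test_planted_outliers_removed(self, rng):
        contigs = [f"c{i}" for i in range(103)]
        cov = dict(zip(contigs, np.concatenate([
            rng.normal(20, 1, 100), [200.0, 210.0, 190.0]])))
        kept, discarded, scores = qc.coverage_outlier_filter(contigs, cov)
        assert set(discarded) >= {"c100", "c101", "c102"}
        assert len(discarded) <= 5

    def test_uniform_coverage_nothing_removed(self):
        contigs = ["a", "b", "c", "d"]
        kept, discarded, _ = qc.coverage_outlier_filter(
            contigs, {c: 10.0 for c in contigs})
        assert kept == contigs and discarded == []

    def test_strict_inequality_at_boundary(self):
        # construct values whose extreme scores exactly 3.5:
        # median 0, MAD 1 -> x = 3.5 / 0.6745
        x = 3.5 / 0.6745
        values = {"a": -1.0, "b": 0.0, "c": 1.0, "d": 0.0, "e": x}
        scores = qc.modified_zscore(list(values.values()))
        assert scores[-1] == pytest.approx(3.5, abs=1e-12)
        kept, discarded, _ = qc.coverage_outlier_filter(list(values), values)
        assert discarded == []  # "greater than 3.5" is strict

    def test_partition_property(self, rng):
        contigs = [f"c{i}" for i in range(50)]
        cov = dict(zip(contigs, rng.lognormal(3, 1, size=50)))
        kept, discarded, _ = qc.coverage_outlier_filter(contigs, cov)
        assert sorted(kept + discarded) == sorted(contigs)
        assert not (set(kept) & set(discarded))

    def test_normal_sample_false_positive_rate(self):
        flagged = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            contigs = [f"c{i}" for i in range(10_000)]
            cov = dict(zip(contigs, rng.normal(50, 5, size=10_000)))
            _, discarded, _ = qc.coverage_outlier_filter(contigs, cov)
            flagged.append(len(discarded) / 10_000)
        assert all(f < 0.005 for f in flagged)

    def test_missing_coverage_fatal(self):
        with pytest.raises(MissingDataError):
            qc.coverage_outlier_filter(["a", "b", "ghost"],
                                       {"a": 1.0, "b": 2.0})

    def test_both_tails_removed(self, rng):
        contigs = [f"c{i}" for i in range(52)]
        cov = dict(zip(contigs, np.concatenate([
            rng.normal(50, 1, 50), [0.5, 500.0]])))
        _, discarded, _ = qc.coverage_outlier_filter(contigs, cov)
        assert {"c50", "c51"} <= set(discarded)


class TestContigMeanCoverage:
    def test_uniform_depth(self):
        depth = pd.DataFrame([("c1", 0, 100, 10)],
                             columns=["contig", "start", "end", "depth"])
        out = qc.contig_mean_coverage(depth, {"c1": 100})
        assert out["c1"] == pytest.approx(10.0)

    def test_half_covered(self):
        depth = pd.DataFrame([("c1", 0, 50, 10)],
                             columns=["contig", "start", "end", "depth"])
        out = qc.contig_mean_coverage(depth, {"c1": 100})
        assert out["c1"] == pytest.approx(5.0)

    def test_windowed_example(self):
        depth = pd.DataFrame([("c1", 0, 100, 4), ("c1", 100, 300, 1)],
                             columns=["contig", "start", "end", "depth"])
        out = qc.contig_mean_coverage(depth, {"c1": 300})
        assert out["c1"] == pytest.approx(2.0)
        assert out["c1"] == pytest.approx(
            per_base_mean_depth_oracle([(0, 100, 4), (100, 300, 1)], 300))

    def test_contig_without_records_is_zero(self):
        depth = pd.DataFrame([("c1", 0, 10, 5)],
                             columns=["contig", "start", "end", "depth"])
        out = qc.contig_mean_coverage(depth, {"c1": 10, "c2": 10})
        assert out["c2"] == 0.0

    def test_unknown_contig_fatal(self):
        depth = pd.DataFrame([("ghost", 0, 10, 5)],
                             columns=["contig", "start", "end", "depth"])
        with pytest.raises(MissingDataError):
            qc.contig_mean_coverage(depth, {"c1": 10})

    def test_matches_per_base_oracle_random(self, rng):
        windows = []
        pos = 0
        for _ in range(10):
            span = int(rng.integers(10, 100))
            windows.append((pos, pos + span, float(rng.integers(0, 30))))
            pos += span
        depth = pd.DataFrame([("c", s, e, d) for s, e, d in windows],
                             columns=["contig", "start", "end", "depth"])
        out = qc.contig_mean_coverage(depth, {"c": pos + 37})
        assert out["c"] == pytest.approx(
            per_base_mean_depth_oracle(windows, pos + 37))


class TestBinModel:
    def test_duplicate_contigs_rejected(self):
        with pytest.raises(ValueError):
            qc.Bin("b", ["c1", "c1"], "polygon")

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ValueError):
            qc.Bin("b", ["c1"], "manual")

    def test_qc_row_fields(self):
        bin_ = qc.Bin("b1", ["c1"], "polygon")
        bin_.qc = qc.EssentialGeneReport(10, 1, n_families_total=20)
        row = qc.bin_qc_row(bin_, {"c1": "ACGTACGT"}, n_discarded=2)
        assert row["n_contigs"] == 1
        assert row["total_bp"] == 8
        assert row["completeness"] == 10
        assert row["n_discarded_outliers"] == 2

    def test_report_invariant(self):
        with pytest.raises(ValueError):
            qc.EssentialGeneReport(5, 6)
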