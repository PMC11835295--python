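import numpy as np
import pandas as pd
import pytest

from flymb import (AnnotationParams, EnrichmentCallParams, GeneTable,
                   IntervalSet, PeakFilterParams, TargetGenomeParams,
                   annotate_peaks_to_genes, consensus_peaks,
                   filter_differential_peaks, gen_interval_set,
                   gen_target_genome, identify_trx_targets,
                   intersect_intervals, mb_enrichment_call,
                   median_of_ratios_normalize, subtract_blacklist)
from conftest import brute_force_overlaps


class TestIntersect:
    def test_partial_overlap_retained(self):
        a = IntervalSet.from_records([("chr2L", 100, 200, "a")])
        b = IntervalSet.from_records([("chr2L", 150, 250, "b")])
        out = intersect_intervals(a, b)
        assert out.records[0][:3] == ("chr2L", 100, 200)

    def test_half_open_adjacency_is_empty(self):
        a = IntervalSet.from_records([("chr2L", 100, 200, "a")])
        b = IntervalSet.from_records([("chr2L", 200, 300, "b")])
        assert len(intersect_intervals(a, b)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        a = gen_interval_set(200, seed=seed)
        b = gen_interval_set(200, seed=seed + 100)
        got = [r[:4] for r in intersect_intervals(a, b).records]
        expected = [a.records[i][:4] for i in brute_force_overlaps(a, b)]
        assert got == expected

    def test_oracle_equivalence_large(self):
        a = gen_interval_set(1000, seed=42)
        b = gen_interval_set(1000, seed=43)
        got = {r[:4] for r in intersect_intervals(a, b).records}
        expected = {a.records[i][:4] for i in brute_force_overlaps(a, b)}
        assert got == expected


def _disjoint_peaks(n, seed, chrom="chr2L"):
    """Random peaks, non-overlapping within the set (peak-caller style)."""
    rng = np.random.default_rng(seed)
    pos, rows = 0, []
    for i in range(n):
        pos += int(rng.integers(1, 300))
        length = int(rng.integers(50, 400))
        rows.append((chrom, pos, pos + length, f"p{i}"))
        pos += length
    return IntervalSet.from_records(rows)


class TestConsensus:
    def test_merged_union(self):
        r1 = IntervalSet.from_records([("chr2L", 100, 200, "a")])
        r2 = IntervalSet.from_records([("chr2L", 150, 250, "b")])
        out = consensus_peaks(r1, r2)
        assert [r[:3] for r in out.records] == [("chr2L", 100, 250)]

    def test_replicate_unique_peak_dropped(self):
        r1 = IntervalSet.from_records([("chr2L", 100, 200, "a"),
                                       ("chr2L", 1000, 1100, "only1")])
        r2 = IntervalSet.from_records([("chr2L", 150, 250, "b")])
        out = consensus_peaks(r1, r2)
        assert len(out) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric(self, seed):
        r1 = _disjoint_peaks(50, seed)
        r2 = _disjoint_peaks(50, seed + 50)
        assert consensus_peaks(r1, r2) == consensus_peaks(r2, r1)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_against_replicate(self, seed):
        r1 = _disjoint_peaks(50, seed)
        r2 = _disjoint_peaks(50, seed + 50)
        c = consensus_peaks(r1, r2)
        assert consensus_peaks(c, r1) == c


class TestBlacklist:
    def test_any_overlap_removes_whole_peak(self):
        peaks = IntervalSet.from_records([("chr2L", 100, 200, "p")])
        bl = IntervalSet.from_records([("chr2L", 150, 160, "bl")])
        assert len(subtract_blacklist(peaks, bl)) == 0

    def test_no_overlap_unchanged(self):
        peaks = IntervalSet.from_records([("chr2L", 100, 200, "p")])
        bl = IntervalSet.from_records([("chr2L", 300, 400, "bl")])
        assert subtract_blacklist(peaks, bl) == peaks

    def test_empty_blacklist_identity(self):
        peaks = gen_interval_set(20, seed=0)
        assert subtract_blacklist(peaks, IntervalSet.empty()) == peaks


class TestPeakFilter:
    def test_default_thresholds(self):
        peaks = IntervalSet.from_records([
            ("chr2L", 0, 100, "keep", np.nan, 0.004, 1.5, "down"),
            ("chr2L", 200, 300, "fdr_fail", np.nan, 0.2, 3.0, "down"),
            ("chr2L", 400, 500, "fc_fail", np.nan, 0.01, 1.1, "down"),
            ("chr2L", 600, 700, "wrong_dir", np.nan, 0.01, 2.0, "up"),
        ])
        out = filter_differential_peaks(peaks, PeakFilterParams(direction="reduced"))
        assert [r[3] for r in out.records] == ["keep"]

    def test_toy_table_three_of_ten(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            passing = i < 3
            rows.append(("chr2L", i * 1000, i * 1000 + 100, f"p{i}", np.nan,
                         0.001 if passing else 0.5,
                         2.0 if passing else 1.05, "down"))
        out = filter_differential_peaks(IntervalSet.from_records(rows))
        assert sorted(r[3] for r in out.records) == ["p0", "p1", "p2"]

    def test_missing_stats_error(self):
        peaks = IntervalSet.from_records([("chr2L", 0, 100, "p")])
        with pytest.raises(ValueError, match="missing"):
            filter_differential_peaks(peaks)

    def test_stricter_fdr_supported(self):
        peaks = IntervalSet.from_records([
            ("chr2L", 0, 100, "p", np.nan, 0.03, 2.0, "down")])
        assert len(filter_differential_peaks(peaks, PeakFilterParams(fdr_max=0.05))) == 1
        assert len(filter_differential_peaks(peaks, PeakFilterParams(fdr_max=0.01))) == 0


class TestAnnotation:
    def test_nearest_tss(self):
        peaks = IntervalSet.from_records([("chr2L", 100, 200, "pk")])
        genes = IntervalSet.from_records([("chr2L", 100, 2000, "near"),
                                          ("chr2L", 400, 2400, "far")])
        assert annotate_peaks_to_genes(peaks, genes)["pk"] == ["near"]

    def test_exact_tie_reports_both(self):
        peaks = IntervalSet.from_records([("chr2L", 190, 210, "pk")])  # midpoint 200
        genes = IntervalSet.from_records([("chr2L", 100, 1000, "left"),
                                          ("chr2L", 300, 1300, "right")])
        assert sorted(annotate_peaks_to_genes(peaks, genes)["pk"]) == ["left", "right"]

    def test_empty_gene_set_error(self):
        peaks = IntervalSet.from_records([("chr2L", 0, 10, "pk")])
        with pytest.raises(ValueError):
            annotate_peaks_to_genes(peaks, IntervalSet.empty())

    def test_window_overlap_mode(self):
        peaks = IntervalSet.from_records([("chr2L", 900, 950, "pk")])
        genes = IntervalSet.from_records([("chr2L", 1000, 3000, "g1"),
                                          ("chr2L", 5000, 7000, "g2")])
        out = annotate_peaks_to_genes(peaks, genes,
                                      AnnotationParams(2000, "window_overlap"))
        assert out["pk"] == ["g1"]

    @pytest.mark.parametrize("seed", range(5))
    def test_nearest_tss_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = IntervalSet.from_records(
            [("chr2L", int(p), int(p) + 500, f"g{i}")
             for i, p in enumerate(np.sort(rng.choice(50_000, 30, replace=False)))])
        peaks = gen_interval_set(40, seed=seed + 10, chroms=("chr2L",), max_pos=50_000)
        got = annotate_peaks_to_genes(peaks, genes)
        for chrom, start, end, name, *_ in peaks.records:
            mid = (start + end) / 2
            dists = {g[3]: abs(g[1] - mid) for g in genes.records}
            best = min(dists.values())
            assert set(got[name]) == {g for g, d in dists.items() if d == best}


class TestFunnel:
    @pytest.mark.parametrize("n_planted", [0, 5])
    def test_planted_recovery(self, n_planted):
        genes, peaks, tf, oc, de, truth = gen_target_genome(
            TargetGenomeParams(n_genes=50, n_planted_targets=n_planted, seed=3))
        res = identify_trx_targets(peaks, tf, oc, de, genes)
        assert set(res.targets) == truth
        assert len(truth) == n_planted

    def test_funnel_counts_monotone(self):
        for seed in range(10):
            genes, peaks, tf, oc, de, truth = gen_target_genome(
                TargetGenomeParams(seed=seed))
            res = identify_trx_targets(peaks, tf, oc, de, genes)
            assert (res.n_reduced_peak_genes >= res.n_with_binding
                    >= res.n_with_reduced_mrna == len(res.targets))

    def test_no_reduced_peaks_gives_empty_funnel(self):
        genes, _, tf, oc, de, _ = gen_target_genome(TargetGenomeParams(seed=1))
        res = identify_trx_targets(IntervalSet.empty(), tf, oc, de, genes)
        assert res.targets == ()
        assert (res.n_reduced_peak_genes, res.n_with_binding,
                res.n_with_reduced_mrna) == (0, 0, 0)

    def test_padj_failure_excluded_at_stage_three(self):
        genes = IntervalSet.from_records([("chr2L", 1000, 3000, "g1")])
        peaks = IntervalSet.from_records([("chr2L", 900, 1100, "pk")])
        tf = IntervalSet.from_records([("chr2L", 950, 1050, "tf")])
        oc = IntervalSet.from_records([("chr2L", 900, 1100, "oc")])
        de = GeneTable(pd.DataFrame([{"gene_id": "g1", "log2fc": -1.0, "padj": 0.9}]))
        res = identify_trx_targets(peaks, tf, oc, de, genes)
        assert res.n_with_binding == 1
        assert res.targets == ()


class TestMedianOfRatios:
    def test_doubled_sample(self):
        counts = np.array([[10, 20], [30, 60], [50, 100]])
        sf, norm = median_of_ratios_normalize(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])
        np.testing.assert_allclose(norm[:, 0], norm[:, 1])

    def test_identical_samples_unit_factors(self):
        counts = np.array([[10, 10], [30, 30]])
        sf, _ = median_of_ratios_normalize(counts)
        np.testing.assert_allclose(sf, [1.0, 1.0])

    @pytest.mark.parametrize("seed", range(3))
    def test_scale_invariance_of_normalized_values(self, seed):
        """Per-sample rescaling is absorbed by the size factors: exactly when
        the scalings have unit geometric mean, and always up to one global
        constant (only relative depth is identifiable)."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 1000, (50, 4)).astype(float)
        scales = np.array([0.5, 2.0, 1.25, 0.8])  # product 1
        _, norm1 = median_of_ratios_normalize(counts)
        _, norm2 = median_of_ratios_normalize(counts * scales)
        np.testing.assert_allclose(norm1, norm2, rtol=1e-10)
        arbitrary = np.array([0.5, 2.0, 1.3, 0.8])
        _, norm3 = median_of_ratios_normalize(counts * arbitrary)
        ratio = norm3 / norm1
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-10)

    def test_no_common_nonzero_gene_error(self):
        with pytest.raises(ValueError):
            median_of_ratios_normalize(np.array([[0, 1], [1, 0]]))


class TestEnrichmentCall:
    @pytest.mark.parametrize("mean_a, mean_b, padj, expected", [
        (200, 50, 0.01, True),   # fold 4, significant
        (75, 50, 0.01, False),   # fold 1.5 below threshold
        (200, 50, 0.2, False),   # fold passes, padj fails
    ])
    def test_calls(self, mean_a, mean_b, padj, expected):
        t = GeneTable(pd.DataFrame([{"gene_id": "g", "mean_a": mean_a,
                                     "mean_b": mean_b, "log2fc": 0.0,
                                     "padj": padj}]))
        out = mb_enrichment_call(t, EnrichmentCallParams())
        assert bool(out.loc[0, "enriched"]) is expected

    def test_zero_reference_mean_infinite_fold(self):
        t = GeneTable(pd.DataFrame([{"gene_id": "g", "mean_a": 10.0,
                                     "mean_b": 0.0, "log2fc": 0.0, "padj": 0.01}]))
        out = mb_enrichment_call(t)
        assert np.isinf(out.loc[0, "fold"])
        assert bool(out.loc[0, "enriched"])
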