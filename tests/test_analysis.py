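import itertools
import math

import numpy as np
import pytest
from scipy import stats

import coexseg as cx
from coexseg.analysis import single_tissue_restricted


def make_matrix(values, arm="2L"):
    values = np.asarray(values, dtype=float)
    return cx.ExpressionMatrix(
        arm,
        [f"g{i}" for i in range(values.shape[0])],
        [f"t{j}" for j in range(values.shape[1])],
        values,
    )


class TestSegmentProfiles:
    def test_singleton_segment_equals_gene_values(self, rng):
        m = make_matrix(rng.normal(size=(4, 3)))
        seg = cx.Segmentation("2L", (1, 3))
        profiles = cx.segment_profiles(seg, m)
        np.testing.assert_array_equal(profiles[0].per_tissue, m.values[0])

    def test_constant_matrix_has_zero_sd(self):
        m = make_matrix(np.full((6, 4), 2.5))
        for p in cx.segment_profiles(cx.Segmentation("2L", (2, 4)), m):
            assert p.sd == 0.0
            assert p.mean == 2.5

    def test_matches_two_pass_mean_sd_oracle(self, rng):
        m = make_matrix(rng.normal(size=(10, 5)))
        seg = cx.Segmentation("2L", (3, 2, 5))
        b = seg.boundaries()
        for p, (i, j) in zip(cx.segment_profiles(seg, m), zip(b[:-1], b[1:])):
            vals = [m.values[i:j, t].sum() / (j - i) for t in range(5)]
            mean = sum(vals) / 5
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 4)
            assert p.mean == pytest.approx(mean, abs=1e-12)
            assert p.sd == pytest.approx(sd, abs=1e-12)

    def test_merged_profile_is_gene_weighted_mean_of_parts(self, rng):
        m = make_matrix(rng.normal(size=(8, 3)))
        parts = cx.segment_profiles(cx.Segmentation("2L", (3, 5)), m)
        merged = cx.segment_profiles(cx.Segmentation("2L", (8,)), m)[0]
        weighted = (3 * parts[0].per_tissue + 5 * parts[1].per_tissue) / 8
        np.testing.assert_allclose(merged.per_tissue, weighted, atol=1e-12)

    def test_invariant_to_tissue_order(self, rng):
        vals = rng.normal(size=(6, 4))
        a = cx.segment_profiles(cx.Segmentation("2L", (6,)), make_matrix(vals))[0]
        b = cx.segment_profiles(cx.Segmentation("2L", (6,)), make_matrix(vals[:, ::-1]))[0]
        assert a.mean == pytest.approx(b.mean) and a.sd == pytest.approx(b.sd)


class TestClassifySegments:
    @staticmethod
    def planted_profiles(sds, n_genes=3):
        out = []
        for k, sd in enumerate(sds):
            per_tissue = np.array([0.0, sd, -sd, 0.0]) + 5.0
            out.append(
                cx.SegmentProfile(k, n_genes, per_tissue, 5.0, float(np.std(per_tissue, ddof=1)))
            )
        return out

    def test_top_quartile_planted_structure(self):
        profiles = self.planted_profiles([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 8.0])
        cx.classify_segments(profiles, dataset_median=5.0)
        classes = [p.klass for p in profiles]
        assert classes.count("tissue-restricted") == 2  # top quartile of 8
        assert classes[-1] == "tissue-restricted" and classes[-2] == "tissue-restricted"
        assert classes[0] == "housekeeping-like"

    def test_single_tissue_restriction(self):
        # above the dataset median in exactly one tissue
        high_one = cx.SegmentProfile(0, 3, np.array([9.0, 1.0, 1.0, 1.0]), 3.0, 4.0)
        rest = self.planted_profiles([0.1, 0.2, 0.3])
        profiles = [high_one] + rest
        cx.classify_segments(profiles, dataset_median=5.0)
        singles = single_tissue_restricted(profiles)
        assert [p.index for p in singles] == [0]
        assert profiles[0].restricted_tissues == {"0"}

    def test_small_segments_unclassified(self):
        profiles = self.planted_profiles([0.1, 0.2, 0.3, 0.4])
        profiles.append(cx.SegmentProfile(4, 1, np.array([1.0, 2, 3, 4]), 2.5, 1.29))
        cx.classify_segments(profiles, dataset_median=2.0)
        assert profiles[-1].klass == "unclassified"

    def test_all_equal_sds_include_ties(self):
        profiles = self.planted_profiles([0.5, 0.5, 0.5, 0.5])
        cx.classify_segments(profiles, dataset_median=5.0)
        assert all(p.klass == "tissue-restricted" for p in profiles)

    def test_fewer_than_four_eligible_reported(self):
        with pytest.raises(ValueError, match="quartile undefined"):
            cx.classify_segments(self.planted_profiles([0.1, 0.2, 0.3]), 5.0)


class TestIntergenicLengthComparison:
    def test_identical_samples(self):
        d, p = cx.compare_intergenic_lengths([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = cx.compare_intergenic_lengths([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_matches_ecdf_gap_oracle(self, rng):
        a = rng.exponential(5, 20)
        b = rng.exponential(9, 20)
        d, _ = cx.compare_intergenic_lengths(a, b)
        grid = np.sort(np.concatenate([a, b]))
        gap = max(
            abs(np.mean(a <= x) - np.mean(b <= x)) for x in grid
        )
        assert d == pytest.approx(gap, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cx.compare_intergenic_lengths([], [1.0])


class TestOrientation:
    @pytest.mark.parametrize(
        "up,down,expected",
        [
            ("+", "+", "same"),
            ("-", "-", "same"),
            ("-", "+", "head-to-head"),
            ("+", "-", "tail-to-tail"),
            (".", "+", None),
        ],
    )
    def test_pair_classification(self, up, down, expected):
        assert cx.classify_pair_orientation(up, down) == expected

    def test_chi2_matches_textbook_formula(self):
        # planted counts: class A (10, 6, 4), class B (5, 10, 5)
        pairs, classes = [], []
        for cls, counts in (("A", (10, 6, 4)), ("B", (5, 10, 5))):
            for orient, n in zip(("same", "head-to-head", "tail-to-tail"), counts):
                strand = {"same": ("+", "+"), "head-to-head": ("-", "+"), "tail-to-tail": ("+", "-")}[orient]
                pairs.extend([strand] * n)
                classes.extend([cls] * n)
        res = cx.orientation_test(pairs, classes, compare=("A", "B"))
        obs = np.array([[10, 6, 4], [5, 10, 5]], dtype=float)
        expected = obs.sum(axis=1)[:, None] * obs.sum(axis=0)[None, :] / obs.sum()
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.dof == 2
        assert res.pvalue == pytest.approx(float(stats.chi2.sf(chi2, 2)), abs=1e-12)

    def test_undefined_strand_excluded_and_counted(self):
        pairs = [("+", "+"), (".", "-"), ("-", "+")]
        classes = ["A", "A", "A"]
        res = cx.orientation_test(pairs + [("+", "-")], classes + ["B"], compare=("A", "B"))
        assert res.n_excluded == 1
        assert res.counts["A"]["same"] == 1


class TestEndpointSharing:
    def test_fisher_point_value(self):
        # 2x2 table [[3,1],[1,3]]: two-sided p = 34/70
        seg = [True] * 4 + [False] * 4
        dom = [True, True, True, False, True, False, False, False]
        table, p, shared = cx.endpoint_sharing_test(seg, dom)
        assert table.tolist() == [[3, 1], [1, 3]]
        assert p == pytest.approx(34 / 70, abs=1e-10)
        assert shared == pytest.approx(3 / 4)

    def test_all_both_is_degenerate(self):
        table, p, shared = cx.endpoint_sharing_test([True] * 6, [True] * 6)
        assert p == 1.0
        assert shared == 1.0

    def test_domain_subset_of_segment_endpoints(self):
        seg = [True, True, True, False]
        dom = [True, True, False, False]
        _, _, shared = cx.endpoint_sharing_test(seg, dom)
        assert shared == 1.0


class TestPeakEnrichment:
    def test_density_per_kilobase(self):
        regions = cx.IntervalSet([("2L", 0, 10_000)], "a")
        peaks = cx.IntervalSet([("2L", i * 1000, i * 1000 + 100) for i in range(5)], "peaks")
        res = cx.peak_enrichment(regions, regions, peaks)
        assert res.density_a == pytest.approx(0.5)
        assert res.enrichment == pytest.approx(1.0)
        assert res.pvalue == 1.0

    def test_overlap_counts_match_quadratic_oracle(self, rng):
        regions_a = cx.IntervalSet(
            [("2L", int(b), int(b) + int(w)) for b, w in zip(rng.integers(0, 50_000, 30), rng.integers(50, 900, 30))],
            "a",
        )
        regions_b = cx.IntervalSet(
            [("2L", int(b), int(b) + int(w)) for b, w in zip(rng.integers(50_000, 100_000, 30), rng.integers(50, 900, 30))],
            "b",
        )
        peaks = cx.IntervalSet(
            [("2L", int(b), int(b) + 200) for b in rng.integers(0, 100_000, 60)], "peaks"
        )
        res = cx.peak_enrichment(regions_a, regions_b, peaks)

        def brute(regions):
            return sum(
                any(pb < e and b < pe for _, b, e in regions)
                for _, pb, pe in peaks
            )

        assert res.count_a == brute(regions_a)
        assert res.count_b == brute(regions_b)

    def test_mask_removes_overlapping_peaks(self):
        regions = cx.IntervalSet([("2L", 0, 10_000)], "a")
        peaks = cx.IntervalSet([("2L", 100, 200), ("2L", 5000, 5100)], "peaks")
        mask = cx.IntervalSet([("2L", 4900, 5050)], "boundary-windows")
        res = cx.peak_enrichment(regions, regions, peaks, mask=mask)
        assert res.n_peaks_used == 1
        assert res.count_a == 1

    def test_nonpeak_count_definition(self):
        # 10 kb of regions, 2 peaks of mean length 500:
        # non-peaks = (10000 - 2*500)/500 = 18
        regions = cx.IntervalSet([("2L", 0, 10_000)], "a")
        peaks = cx.IntervalSet([("2L", 0, 500), ("2L", 1000, 1500)], "peaks")
        res = cx.peak_enrichment(regions, regions, peaks)
        assert res.table[0].tolist() == [2, 18]
        literal = cx.peak_enrichment(regions, regions, peaks, literal_nonpeaks=True)
        assert literal.table[0].tolist() == [2, 20]  # (10000 - 2)/500 rounded

    def test_zero_length_regions_rejected(self):
        with pytest.raises(ValueError):
            cx.peak_enrichment(
                cx.IntervalSet([("2L", 5, 5)], "a"),
                cx.IntervalSet([("2L", 0, 10)], "b"),
                cx.IntervalSet([("2L", 0, 5)], "p"),
            )

    def test_bonferroni_batch(self):
        regions_a = cx.IntervalSet([("2L", 0, 1000)], "a")
        regions_b = cx.IntervalSet([("2L", 1000, 2000)], "b")
        peak_sets = {
            "x": cx.IntervalSet([("2L", 10, 20)], "x"),
            "y": cx.IntervalSet([("2L", 1500, 1510)], "y"),
        }
        out = cx.peak_enrichment_batch(regions_a, regions_b, peak_sets)
        for res, p_corr in out.values():
            assert p_corr == pytest.approx(min(res.pvalue * 2, 1.0))


class TestShuffleSegmentation:
    def test_all_singletons_impossible(self):
        with pytest.raises(RuntimeError):
            cx.shuffle_segmentation(cx.Segmentation("a", (1, 1, 1, 1)), rng=0, max_tries=50)

    def test_lengths_preserved_and_boundaries_disjoint(self):
        seg = cx.Segmentation("a", (3, 2, 5))
        for seed in range(20):
            shuf = cx.shuffle_segmentation(seg, rng=seed)
            assert sorted(shuf.lengths) == [2, 3, 5]
            assert not (shuf.internal_boundaries() & seg.internal_boundaries())

    def test_uniform_over_valid_permutations(self):
        lengths = (1, 2, 3, 4, 5, 6)
        seg = cx.Segmentation("a", lengths)
        original = seg.internal_boundaries()
        valid = set()
        for perm in itertools.permutations(lengths):
            cand = cx.Segmentation("a", perm)
            if not (cand.internal_boundaries() & original):
                valid.add(perm)
        assert valid
        rng = np.random.default_rng(99)
        counts: dict[tuple, int] = {}
        n_draws = 10_000
        for _ in range(n_draws):
            shuf = cx.shuffle_segmentation(seg, rng)
            assert shuf.lengths in valid
            counts[shuf.lengths] = counts.get(shuf.lengths, 0) + 1
        observed = np.array([counts.get(p, 0) for p in sorted(valid)])
        res = stats.chisquare(observed)
        assert res.pvalue > 0.001


class TestTermEnrichment:
    def test_planted_enrichment_found(self):
        # genes 0-3 form a segment, all carry term X; X is rare elsewhere
        genes = [f"g{i}" for i in range(20)]
        gene_terms = {g: {"X"} for g in genes[:4]}
        gene_terms["g10"] = {"X"}
        seg = cx.Segmentation("a", (4, 8, 8))
        res = cx.term_enrichment(seg, genes, gene_terms, alpha=0.05, n_shuffles=5, rng=1)
        assert any(r["segment"] == 0 and r["term"] == "X" for r in res.significant)
        assert res.n_enriched_segments >= 1

    def test_single_carrier_never_significant(self):
        # term Y carried by one gene genome-wide: p < alpha yet excluded
        genes = [f"g{i}" for i in range(20)]
        gene_terms = {"g0": {"Y"}}
        seg = cx.Segmentation("a", (2, 9, 9))
        res = cx.term_enrichment(seg, genes, gene_terms, alpha=0.99, n_shuffles=3, rng=2)
        tested = [r for r in res.tests if r["term"] == "Y"]
        assert tested and tested[0]["p_bonferroni"] < 0.99
        assert not any(r["term"] == "Y" for r in res.significant)

    def test_pvalue_matches_hypergeometric_sum(self):
        genes = [f"g{i}" for i in range(12)]
        gene_terms = {g: {"Z"} for g in ("g0", "g1", "g5", "g9")}
        seg = cx.Segmentation("a", (3, 9))
        res = cx.term_enrichment(seg, genes, gene_terms, alpha=1.1, n_shuffles=2, rng=3)
        rec = next(r for r in res.tests if r["segment"] == 0 and r["term"] == "Z")
        # P(X >= 2) drawing 3 from 12 with 4 marked, by explicit enumeration
        N, K, n = 12, 4, 3
        p_exact = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n) for k in (2, 3)
        )
        assert rec["p_raw"] == pytest.approx(p_exact, abs=1e-12)

    def test_empty_term_map_rejected(self):
        with pytest.raises(ValueError):
            cx.term_enrichment(cx.Segmentation("a", (2, 2)), ["g0", "g1", "g2", "g3"], {})
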