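"""Peak-to-gene links: correlation, permutation null, FDR, OLS and LOF."""

import numpy as np
import pandas as pd
import pytest

from sesvlink.intervals import GeneModel, GenomicInterval
from sesvlink.links import (
    bh_fdr,
    build_consensus_matrix,
    candidate_pairs,
    least_squares_fit,
    lof_scores,
    pearson_link,
    permutation_null_p,
    se_to_gene_filter,
    sv_expression_association,
)


class TestCandidatePairs:
    def _gene(self, gid, tss, strand="+"):
        return GeneModel(gid, gid, GenomicInterval("chr1", tss, tss + 10_000, strand))

    def test_distance_boundary(self):
        regions = [("p1", GenomicInterval("chr1", 1_000_000, 1_001_000))]
        kept = self._gene("near", 1_000_000 + 1_000 + 500_000)  # exactly 500 kb
        dropped = self._gene("far", 1_000_000 + 1_000 + 500_001)
        pairs = candidate_pairs(regions, [kept, dropped])
        assert [(p, g) for p, g, _ in pairs] == [("p1", "near")]

    def test_tss_inside_peak_distance_zero(self):
        regions = [("p1", GenomicInterval("chr1", 1_000, 3_000))]
        pairs = candidate_pairs(regions, [self._gene("g", 2_000)])
        assert pairs == [("p1", "g", 0)]

    def test_matches_bruteforce_distance_scan(self, rng):
        regions = [
            (f"p{k}", GenomicInterval("chr1", int(s), int(s) + int(rng.integers(500, 5_000))))
            for k, s in enumerate(rng.integers(0, 5_000_000, 40))
        ]
        genes = [self._gene(f"g{k}", int(t)) for k, t in
                 enumerate(rng.integers(0, 5_000_000, 40))]
        got = {(p, g) for p, g, _ in candidate_pairs(regions, genes)}
        expected = set()
        for pid, iv in regions:
            for g in genes:
                if iv.distance_to_point(g.tss) <= 500_000:
                    expected.add((pid, g.gene_id))
        assert got == expected


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_link(x, x) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert pearson_link(np.arange(5.0), np.full(5, 2.0)) is None

    def test_hand_formula_five_points(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_link(x, y) == pytest.approx(num / den)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = pearson_link(x, y)
        assert pearson_link(3.5 * x + 2, y) == pytest.approx(r0)
        assert pearson_link(x, 0.1 * y - 7) == pytest.approx(r0)


class TestPermutationNull:
    def test_attainable_minimum_with_identical_vectors(self):
        x = np.arange(30.0)
        rng = np.random.default_rng(0)
        r, p, _ = permutation_null_p(x, x, n_perm=999, rng=rng)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_two_sided_symmetry_under_negation(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        _, p1, _ = permutation_null_p(x, y, n_perm=500, rng=np.random.default_rng(11))
        _, p2, _ = permutation_null_p(x, -y, n_perm=500, rng=np.random.default_rng(11))
        assert p1 == p2

    def test_null_values_bounded_by_one(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        _, _, null = permutation_null_p(x, y, n_perm=200, rng=rng, keep_null=True)
        assert null.n_perm == 200
        assert np.all(np.abs(null.null_r) <= 1 + 1e-12)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_stepup_textbook_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    def test_matches_hand_stepup_on_random_sets(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.uniform(1e-6, 1.0, m)
            got = bh_fdr(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                running = min(running, p[i] * m / (rank + 1))
                adj[i] = running
            assert np.allclose(got, adj)
            assert np.all(got >= p - 1e-12)  # adjusted never below raw


class TestLeastSquares:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        slope, intercept = least_squares_fit(x, 2 * x + 1)
        assert (slope, intercept) == (pytest.approx(2.0), pytest.approx(1.0))

    def test_constant_y_zero_slope(self):
        slope, _ = least_squares_fit(np.array([-2.0, -1, 1, 2]), np.full(4, 3.0))
        assert slope == pytest.approx(0.0)

    def test_constant_x_is_error(self):
        with pytest.raises(ValueError):
            least_squares_fit(np.full(4, 1.0), np.arange(4.0))

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        slope, intercept = least_squares_fit(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert slope == pytest.approx(beta[0])
        assert intercept == pytest.approx(beta[1])


class TestLOF:
    def test_uniform_grid_interior_near_one(self):
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        lof = lof_scores(pts, k=10, standardize=False)
        interior = [i for i, (x, y) in enumerate(pts) if 2 <= x <= 7 and 2 <= y <= 7]
        assert np.all(lof[interior] > 0.8)
        assert np.all(lof[interior] < 1.2)

    def test_isolated_point_has_max_score(self, rng):
        cluster = rng.normal(0, 1, size=(50, 2))
        pts = np.vstack([cluster, [[30.0, 30.0]]])
        lof = lof_scores(pts, k=10, standardize=False)
        assert lof.argmax() == 50
        assert lof[50] > 1.5

    def test_n_equal_k_is_error(self):
        with pytest.raises(ValueError):
            lof_scores(np.zeros((10, 2)), k=10)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.neighbors import LocalOutlierFactor

        for _ in range(20):
            n = int(rng.integers(15, 60))
            pts = rng.normal(size=(n, 2))
            k = int(rng.integers(3, min(11, n - 1)))
            ours = lof_scores(pts, k=k, standardize=False)
            ref = LocalOutlierFactor(n_neighbors=k).fit(pts)
            assert np.allclose(ours, -ref.negative_outlier_factor_, rtol=1e-6)


class TestSEGeneFilter:
    def _links(self):
        return pd.DataFrame(
            {
                "peak_id": ["p1", "p2", "p3", "p4"],
                "gene_id": ["gA", "gB", "gC", "gA"],
                "r": [0.9, 0.8, 0.95, 0.5],
                "p": [0.001, 0.001, 0.001, 0.02],
                "distance_to_tss": [0, 0, 0, 100],
                "in_se": [True, True, False, True],
                "has_sv": [True, False, True, True],
                "fdr": [0.01, 0.01, 0.06, 0.04],
            }
        )

    def test_requires_se_and_sv_annotation(self):
        out = se_to_gene_filter(self._links(), {"gA", "gC"}, {"gA", "gC"})
        assert out["gene_id"].tolist() == ["gA"]  # gB lacks SV, gC fails FDR

    def test_fdr_threshold_is_strict(self):
        links = self._links()
        links.loc[2, "fdr"] = 0.05  # exactly at the cut -> excluded
        out = se_to_gene_filter(links, {"gC"}, {"gC"})
        assert len(out) == 0

    def test_best_link_kept_per_gene(self):
        out = se_to_gene_filter(self._links(), {"gA"}, {"gA"})
        assert out.loc[0, "peak_id"] == "p1"  # fdr 0.01 beats 0.04


class TestSVExpressionAssociation:
    def _expr(self, rng, shift=0.0):
        vals = rng.normal(5, 1, size=(3, 40))
        vals[0, :10] += shift  # gene g0 carriers are samples 0..9
        return pd.DataFrame(vals, index=["g0", "g1", "g2"],
                            columns=[f"S{i}" for i in range(40)])

    def test_null_genes_unchanged(self, rng):
        expr = self._expr(rng)
        carriers = {g: {f"S{i}" for i in range(10)} for g in expr.index}
        out = sv_expression_association(expr, carriers)
        assert set(out["status"]) == {"unchanged"}

    def test_planted_shift_called_elevated(self, rng):
        expr = self._expr(rng, shift=3.0)
        carriers = {"g0": {f"S{i}" for i in range(10)}}
        out = sv_expression_association(expr, carriers).set_index("gene_id")
        assert out.loc["g0", "status"] == "elevated"
        # genes without enough carriers are not tested
        assert np.isnan(out.loc["g1", "p"])

    def test_matches_independent_t_and_bh(self, rng):
        from scipy import stats

        expr = self._expr(rng, shift=2.0)
        carriers = {g: {f"S{i}" for i in range(10)} for g in expr.index}
        out = sv_expression_association(expr, carriers).set_index("gene_id")
        pvals = {}
        for g in expr.index:
            a = expr.loc[g, [f"S{i}" for i in range(10)]]
            b = expr.loc[g, [f"S{i}" for i in range(10, 40)]]
            pvals[g] = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert np.allclose(out["p"], [pvals[g] for g in expr.index])
        assert np.allclose(out["fdr"], bh_fdr([pvals[g] for g in expr.index]))


class TestConsensusMatrix:
    def test_overlapping_peaks_merge_and_signals_sum(self):
        iv = GenomicInterval
        peaks = {
            "S1": [(iv("chr1", 100, 300), 2.0), (iv("chr1", 250, 400), 3.0)],
            "S2": [(iv("chr1", 150, 350), 5.0), (iv("chr2", 0, 100), 1.0)],
        }
        regions, signal = build_consensus_matrix(peaks)
        assert [(r.chrom, r.start, r.end) for _, r in regions] == [
            ("chr1", 100, 400), ("chr2", 0, 100)]
        rid1, rid2 = regions[0][0], regions[1][0]
        assert signal.loc[rid1, "S1"] == 5.0  # both S1 peaks sum
        assert signal.loc[rid1, "S2"] == 5.0
        assert signal.loc[rid2, "S1"] == 0.0
        assert signal.loc[rid2, "S2"] == 1.0

    def test_empty_input(self):
        regions, signal = build_consensus_matrix({"S1": []})
        assert regions == [] and signal.empty
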