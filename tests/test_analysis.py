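"""Population analyses: PCA of dynamics, hull overlap, ridge similarity."""

import numpy as np
import pandas as pd
import pytest

from glidernet import analysis as an
from glidernet.surrogates import TargetPatterns


class TestDynamicsPCA:
    def test_rank_one_population_loads_on_first_component(self):
        base = np.array([1.0, 0.8, 0.6, 0.5, 0.4])
        courses = np.stack([base, 2 * base, base, 3 * base, 0.5 * base + 0.2])
        emb = an.dynamics_pca(courses)
        assert emb.variance_explained[0] > 0.999

    def test_two_temporal_patterns_need_two_components(self):
        a = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        b = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        rng = np.random.default_rng(0)
        w = rng.uniform(0.2, 1.0, size=(30, 2))
        courses = w @ np.stack([a, b])
        emb = an.dynamics_pca(courses)
        assert emb.variance_explained[:2].sum() > 0.999
        assert emb.variance_explained.sum() == pytest.approx(1.0)

    def test_reconstruction_from_all_components_is_exact(self):
        rng = np.random.default_rng(1)
        courses = rng.uniform(0.1, 1.0, size=(12, 5))
        emb = an.dynamics_pca(courses)
        recon = emb.scores @ emb.components + emb.mean_course
        normalized = courses / courses.max(axis=1, keepdims=True)
        assert np.allclose(recon, normalized, atol=1e-8)

    def test_onset_shift_advances_neural_courses(self):
        course = np.array([0.1, 0.9, 0.5, 0.3, 0.2])
        emb = an.dynamics_pca(
            np.stack([course, course]), shift_bins=np.array([0, 1])
        )
        # the shifted course peaks one bin earlier; after max-normalization
        # the two rows differ
        assert not np.allclose(emb.scores[0], emb.scores[1])

    def test_zero_course_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            an.dynamics_pca(np.zeros((3, 5)))


class TestConvexHullOverlap:
    def test_identical_sets_overlap_fully(self):
        pts = np.random.default_rng(2).normal(size=(20, 2))
        assert an.convex_hull_overlap(pts, pts) == pytest.approx(1.0)

    def test_disjoint_sets_do_not_overlap(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(15, 2)) + 100.0
        assert an.convex_hull_overlap(a, b) == 0.0

    def test_matches_rejection_sampling_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(40, 2)) + 0.8
        frac = an.convex_hull_overlap(a, b)
        from shapely.geometry import MultiPoint, Point

        hull_a = MultiPoint([tuple(p) for p in a]).convex_hull
        hull_b = MultiPoint([tuple(p) for p in b]).convex_hull
        lo = np.array(hull_a.bounds[:2])
        hi = np.array(hull_a.bounds[2:])
        samples = lo + rng.uniform(size=(200_000, 2)) * (hi - lo)
        inside_a = np.array([hull_a.contains(Point(*s)) for s in samples[:20000]])
        inside_b = np.array([hull_b.contains(Point(*s)) for s in samples[:20000]])
        mc = inside_b[inside_a].mean()
        assert frac == pytest.approx(mc, abs=0.01)

    def test_degenerate_hull_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate"):
            an.convex_hull_overlap(line, line)


class TestRidgeSimilarity:
    def _data(self, seed=0, n_src=20, n_tgt=6, noise=0.1):
        rng = np.random.default_rng(seed)
        G = rng.normal(size=(35, n_src))
        B = rng.normal(size=(n_src, n_tgt))
        Y = G @ B + noise * rng.normal(size=(35, n_tgt))
        return G, Y

    def test_matches_closed_form_solution(self):
        G, Y = self._data()
        res = an.ridge_similarity(G, Y, ridge_lambda=0.2)
        Gz = (G - G.mean(axis=0)) / G.std(axis=0)
        Yc = Y - Y.mean(axis=0)
        beta = np.linalg.solve(Gz.T @ Gz + 0.2 * np.eye(G.shape[1]), Gz.T @ Yc)
        assert np.allclose(res.beta, beta, atol=1e-6)

    def test_small_lambda_limit_is_ordinary_least_squares(self):
        G, Y = self._data(seed=1, n_src=10)
        res = an.ridge_similarity(G, Y, ridge_lambda=1e-10)
        Gz = (G - G.mean(axis=0)) / G.std(axis=0)
        Yc = Y - Y.mean(axis=0)
        beta_ols = np.linalg.lstsq(Gz, Yc, rcond=None)[0]
        assert np.allclose(res.beta, beta_ols, atol=1e-6)

    def test_exact_linear_mixture_is_recovered(self):
        G, Y = self._data(seed=2, noise=0.0)
        res = an.ridge_similarity(G, Y, ridge_lambda=1e-8)
        assert res.r_mean > 0.99

    def test_zero_variance_target_excluded_with_warning(self):
        G, Y = self._data(seed=3)
        Y[:, 2] = 5.0
        with pytest.warns(UserWarning, match="zero variance"):
            res = an.ridge_similarity(G, Y)
        assert np.isnan(res.r_per_target[2])
        assert np.isfinite(res.r_mean)

    def test_similarity_invariant_to_source_unit_permutation(self):
        G, Y = self._data(seed=4)
        res = an.ridge_similarity(G, Y)
        perm = np.random.default_rng(5).permutation(G.shape[1])
        res_p = an.ridge_similarity(G[:, perm], Y)
        assert res_p.r_mean == pytest.approx(res.r_mean, abs=1e-10)
        inv = np.argsort(perm)  # position of original source 0 after permuting
        assert np.allclose(res_p.beta[inv[0]], res.beta[0], atol=1e-10)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            an.ridge_similarity(np.ones((35, 3)), np.ones((30, 2)))


class TestFormMotionCorrelations:
    def _table(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {c: rng.normal(size=n) for c in an.TEXTURE_INDEX_COLUMNS}
        )
        for c in an.MOTION_INDEX_COLUMNS:
            df[c] = rng.normal(size=n)
        return df

    def test_duplicated_index_correlates_perfectly(self):
        df = self._table()
        df["SSIt"] = df["TSI_even"]
        fm = an.form_motion_correlations(df)
        assert fm.loc["TSI_even", "SSIt"] == pytest.approx(1.0)

    def test_independent_indices_are_uncorrelated(self):
        fm = an.form_motion_correlations(self._table(n=1000, seed=1))
        assert np.nanmax(np.abs(fm.to_numpy(dtype=float))) < 0.12

    def test_sign_flip_negates_a_row(self):
        df = self._table(seed=2)
        fm = an.form_motion_correlations(df)
        df2 = df.copy()
        df2["TSI_odd"] *= -1.0
        fm2 = an.form_motion_correlations(df2)
        assert np.allclose(
            fm2.loc["TSI_odd"].astype(float), -fm.loc["TSI_odd"].astype(float)
        )

    def test_constant_column_flagged(self):
        df = self._table(seed=3)
        df["OSI"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fm = an.form_motion_correlations(df)
        assert fm["OSI"].isna().all()

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="3 units"):
            an.form_motion_correlations(self._table(n=2))


class TestCounterfactualSwap:
    def _targets(self):
        rng = np.random.default_rng(5)
        return TargetPatterns(
            values=rng.uniform(size=(7, 5)), rate_min=0.0, rate_max=1.0
        )

    CLASSES = [
        "random", "white_triangle", "black_triangle", "even", "odd", "wye", "foot",
    ]

    def test_double_swap_is_identity(self):
        tp = self._targets()
        twice = an.counterfactual_swap(
            an.counterfactual_swap(tp, self.CLASSES), self.CLASSES
        )
        assert np.array_equal(twice.values, tp.values)

    def test_swap_exchanges_exactly_the_two_classes(self):
        tp = self._targets()
        out = an.counterfactual_swap(tp, self.CLASSES)
        ia, ib = self.CLASSES.index("black_triangle"), self.CLASSES.index("even")
        assert np.array_equal(out.values[ia], tp.values[ib])
        assert np.array_equal(out.values[ib], tp.values[ia])
        mask = np.ones(7, dtype=bool)
        mask[[ia, ib]] = False
        assert np.array_equal(out.values[mask], tp.values[mask])
        # multiset of values untouched
        assert np.array_equal(np.sort(out.values.ravel()), np.sort(tp.values.ravel()))

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            an.counterfactual_swap(self._targets(), ["a", "b"], "even", "a")
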