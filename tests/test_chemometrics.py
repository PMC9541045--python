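"""PCA-fed LDA: oracles, sign conventions, selection, recovery properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramanmuscle as rm
from ramanmuscle.preprocess import SpectralMatrix
from ramanmuscle.synth import UP_CENTERS


def _matrix(X):
    meta = [
        rm.SpectrumMetadata(f"m{i}", "g", acquisition_id=f"a{i}")
        for i in range(X.shape[0])
    ]
    return SpectralMatrix(np.arange(X.shape[1], dtype=float), X, meta)


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, -1.0]) + rng.normal(0, 1e-4, (10, 3))
        pca = rm.fit_pca(_matrix(X), 2)
        assert pca.explained_variance_ratio[0] > 0.99

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        pca = rm.fit_pca(_matrix(X), 4)
        recon = pca.mean + pca.scores @ pca.loadings
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_matches_covariance_eigendecomposition_oracle(self):
        X = np.array(
            [[2, 0, 1], [4, 1, 3], [1, 5, 2], [3, 2, 8], [0, 4, 4], [5, 3, 1]],
            dtype=float,
        )
        pca = rm.fit_pca(_matrix(X), 3)
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(3):
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(pca.loadings[k], v, atol=1e-8)
            expected_scores = (X - X.mean(axis=0)) @ v
            np.testing.assert_allclose(pca.scores[:, k], expected_scores, atol=1e-8)
        np.testing.assert_allclose(
            pca.explained_variance_ratio, evals / evals.sum(), atol=1e-10
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_loadings_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 6))
        pca = rm.fit_pca(_matrix(X), 5)
        np.testing.assert_allclose(
            pca.loadings @ pca.loadings.T, np.eye(5), atol=1e-8
        )
        assert np.all(np.diff(pca.explained_variance_ratio) <= 1e-12)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            rm.fit_pca(_matrix(np.random.default_rng(0).normal(size=(4, 3))), 4)


class TestSelection:
    def test_perfectly_separating_pc_selected(self):
        rng = np.random.default_rng(2)
        n = 60
        scores = rng.normal(0, 1, (n, 10))
        groups = ["A"] * 30 + ["B"] * 30
        scores[:30, 0] = 1.0 + 0.01 * rng.normal(size=30)
        scores[30:, 0] = -1.0 + 0.01 * rng.normal(size=30)
        pca = rm.PCAModel(np.zeros(10), np.eye(10), scores, np.full(10, 0.1))
        sel = rm.select_components(pca, groups)
        assert 0 in sel.selected and not sel.fallback_used

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pvals=st.lists(
            st.floats(1e-6, 1.0, exclude_max=False), min_size=10, max_size=10
        )
    )
    def test_bh_matches_step_up_oracle(self, pvals):
        """BH decisions equal a brute-force step-up enumeration."""
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        q = 0.01
        reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
        # oracle: sort p, find largest k with p_(k) <= k*q/m, reject those
        m = p.size
        order = np.argsort(p)
        ks = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * q / m))
        expected = np.zeros(m, bool)
        if ks.size:
            expected[order[: ks.max() + 1]] = True
        np.testing.assert_array_equal(reject, expected)

    def test_fallback_on_null_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(40, 10))
        pca = rm.PCAModel(np.zeros(10), np.eye(10), scores, np.full(10, 0.1))
        sel = rm.select_components(pca, ["A"] * 20 + ["B"] * 20)
        assert sel.fallback_used and sel.selected.size == 1
        assert sel.selected[0] == np.argmin(sel.p_values)

    def test_empty_group_rejected(self):
        pca = rm.PCAModel(np.zeros(3), np.eye(3), np.ones((4, 3)), np.full(3, 0.3))
        with pytest.raises(ValueError):
            rm.select_components(pca, ["A"] * 4)


class TestLDA:
    def test_isotropic_case_reduces_to_mean_difference(self):
        rng = np.random.default_rng(0)
        n = 200
        X = rng.normal(size=(n, 3))
        X[n // 2:, 0] += 4.0
        groups = ["A"] * (n // 2) + ["B"] * (n // 2)
        model = rm.fit_lda(X, groups)
        cos = abs(model.weights @ np.array([1.0, 0, 0]))
        assert cos > 0.99

    def test_null_case_no_spurious_separation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2000, 2))
        groups = ["A"] * 1000 + ["B"] * 1000
        model = rm.fit_lda(X, groups)
        d = model.scores[1000:].mean() - model.scores[:1000].mean()
        assert abs(d) / model.scores.std() < 0.2

    def test_matches_closed_form_oracle_on_fixed_points(self):
        X = np.array(
            [[0, 0], [1, 0], [0, 1], [1, 1], [3, 2], [4, 2], [3, 3], [4, 3]],
            dtype=float,
        )
        groups = ["A"] * 4 + ["B"] * 4
        model = rm.fit_lda(X, groups)
        mu1, mu2 = X[:4].mean(axis=0), X[4:].mean(axis=0)
        Sw = ((X[:4] - mu1).T @ (X[:4] - mu1) + (X[4:] - mu2).T @ (X[4:] - mu2)) / 6
        w_oracle = np.linalg.inv(Sw) @ (mu2 - mu1)
        w_oracle /= np.linalg.norm(w_oracle)
        np.testing.assert_allclose(model.weights, w_oracle, atol=1e-10)
        # independent cross-check: sklearn's LDA direction is parallel
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        skl = LinearDiscriminantAnalysis(solver="eigen").fit(X, groups)
        v = skl.coef_.ravel() / np.linalg.norm(skl.coef_)
        assert abs(v @ model.weights) == pytest.approx(1.0, abs=1e-8)

    def test_positive_group_has_higher_mean_score(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2))
        X[20:] += [2.0, -1.0]
        model = rm.fit_lda(X, ["first"] * 20 + ["second"] * 20)
        assert model.group_order == ("first", "second")
        assert model.scores[20:].mean() > model.scores[:20].mean()
        assert model.scores.mean() == pytest.approx(0.0, abs=1e-10)


class TestLoading:
    def test_single_component_identity(self):
        pca = rm.PCAModel(np.zeros(5), np.arange(10.0).reshape(2, 5), None, None)
        sel = rm.SelectionResult(2, np.array([0.001, 0.5]), 0.01, np.array([1]))
        model = rm.DiscriminantModel(sel, np.array([1.0]), None, ("A", "B"))
        np.testing.assert_array_equal(rm.ldf_loading(pca, model), pca.loadings[1])

    def test_zero_weights_give_zero_loading(self):
        pca = rm.PCAModel(np.zeros(4), np.eye(3, 4), None, None)
        sel = rm.SelectionResult(3, np.zeros(3), 0.01, np.array([0, 2]))
        model = rm.DiscriminantModel(sel, np.zeros(2), None, ("A", "B"))
        np.testing.assert_array_equal(rm.ldf_loading(pca, model), np.zeros(4))

    def test_dimension_mismatch_rejected(self):
        pca = rm.PCAModel(np.zeros(4), np.eye(3, 4), None, None)
        sel = rm.SelectionResult(3, np.zeros(3), 0.01, np.array([0, 2]))
        model = rm.DiscriminantModel(sel, np.zeros(3), None, ("A", "B"))
        with pytest.raises(ValueError, match="mismatch"):
            rm.ldf_loading(pca, model)

    def test_fixed_seed_loading_recovers_injected_bands(self, default_fit, default_matrix):
        """Top positive peaks sit on exercised-up bands; the most negative
        on the suppressed 951/961 cm^-1 alpha-helix bands."""
        from scipy.signal import find_peaks

        _, model = default_fit
        grid = default_matrix.grid
        loading = model.ldf_loading
        pk, props = find_peaks(loading, height=0)
        top = grid[pk[np.argsort(props["peak_heights"])[::-1][:10]]]
        hits = sum(any(abs(c - t) <= 6 for t in top) for c in UP_CENTERS)
        assert hits >= 8
        most_negative = grid[np.argmin(loading)]
        assert min(abs(most_negative - c) for c in (951, 961)) <= 6


class TestPipeline:
    def test_end_to_end_separates_groups(self, default_fit, default_matrix):
        pca, model = default_fit
        assert model.selection.selected.size >= 1
        g = default_matrix.group_labels
        d = model.scores[g == "exercised"].mean() - model.scores[g == "unexercised"].mean()
        pooled = model.scores.std(ddof=1)
        assert d / pooled > 1.0  # standardized separation well above noise

    def test_relabeled_null_uses_fallback_with_small_separation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 30))
        meta = [
            rm.SpectrumMetadata(f"m{i}", "A" if i < 20 else "B",
                                acquisition_id=f"a{i}")
            for i in range(40)
        ]
        mat = SpectralMatrix(np.arange(30.0), X, meta)
        pca, model = rm.fit_pipeline(mat)
        assert model.selection.fallback_used or model.selection.selected.size <= 2

    def test_deterministic_given_same_matrix(self, default_matrix):
        pca1, m1 = rm.fit_pipeline(default_matrix)
        pca2, m2 = rm.fit_pipeline(default_matrix)
        np.testing.assert_array_equal(m1.scores, m2.scores)
        np.testing.assert_array_equal(m1.ldf_loading, m2.ldf_loading)
        np.testing.assert_array_equal(pca1.loadings, pca2.loadings)

    def test_scores_invariant_to_joint_rotation(self):
        """Rotating the feature space must not change LDF score rankings."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 6))
        X[30:, :2] += [1.5, -1.0]
        meta_a = [rm.SpectrumMetadata(f"m{i}", "A" if i < 30 else "B",
                                      acquisition_id=f"a{i}") for i in range(60)]
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        mat1 = SpectralMatrix(np.arange(6.0), X, meta_a)
        mat2 = SpectralMatrix(np.arange(6.0), X @ Q.T, meta_a)
        _, m1 = rm.fit_pipeline(mat1, n_candidates=5)
        _, m2 = rm.fit_pipeline(mat2, n_candidates=5)
        r = np.corrcoef(m1.scores, m2.scores)[0, 1]
        assert abs(r) > 0.99

    def test_separation_monotone_in_effect_size(self):
        """Larger covariate-effect coupling yields larger group separation.

        Standardized by the reference-group score spread: raising beta also
        widens the exercised group (its effect magnitudes track the spread
        of running distances), so pooled-within standardization would
        confound the comparison.
        """
        import dataclasses

        sep = []
        for beta in (0.1, 0.5, 1.0):
            ds = []
            for seed in (1, 2, 3, 4, 5):
                cfg = dataclasses.replace(rm.default_config(seed), covariate_beta=beta)
                cohort, _ = rm.generate_cohort(cfg, ["unexercised", "exercised"])
                mat = rm.preprocess_cohort(cohort)
                _, model = rm.fit_pipeline(mat)
                g = mat.group_labels
                s1 = model.scores[g == "unexercised"]
                s2 = model.scores[g == "exercised"]
                ds.append((s2.mean() - s1.mean()) / s1.std(ddof=1))
            sep.append(np.mean(ds))
        assert sep[0] < sep[1] < sep[2]
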