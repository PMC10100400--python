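"""PCA and OPLS-DA engine: oracle equivalence, invariants, recovery."""

import numpy as np
import pytest

import orbimet as om
from orbimet.chemometrics import encode_labels, fit_oplsda, fit_pca, permutation_test
from orbimet.containers import DataError

from conftest import nipals_pls1


def two_group_labels(n_per):
    return np.array(["necrotic"] * n_per + ["viable"] * n_per)


class TestPca:
    def test_rank_one_data_fully_explained(self):
        u = np.arange(6.0)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        model = fit_pca(u @ v, n_components=1)
        assert model.explained_R2X[-1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 10))
        model = fit_pca(X, n_components=3)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(3):
            ref = U[:, a] * s[a]
            sign = np.sign(ref @ model.scores[:, a])
            np.testing.assert_allclose(model.scores[:, a], sign * ref, atol=1e-8)
            np.testing.assert_allclose(model.loadings[:, a], sign * Vt[a], atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        model = fit_pca(rng.normal(size=(9, 12)), n_components=4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-8)

    def test_reconstruction_preserves_feature_means(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 5))
        model = fit_pca(X, n_components=2)
        recon = model.scores @ model.loadings.T + model.mean
        np.testing.assert_allclose(recon.mean(axis=0), X.mean(axis=0), atol=1e-9)

    def test_r2x_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(8)
        model = fit_pca(rng.normal(size=(10, 6)), n_components=5)
        assert np.all(np.diff(model.explained_R2X) >= -1e-12)
        assert model.explained_R2X[-1] <= 1 + 1e-12

    def test_rank_deficient_request_reduced_with_warning(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning, match="reduced"):
            model = fit_pca(rng.normal(size=(4, 10)), n_components=8)
        assert model.scores.shape[1] == 3

    def test_pca_q2_high_for_structured_data(self, benchmark_preprocessed):
        model = fit_pca(benchmark_preprocessed.scaled, n_components=2)
        assert model.Q2 > 0.0


class TestOplsdaCore:
    def test_zero_orthogonal_equals_nipals_pls1(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(8, 12))
        labels = two_group_labels(4)
        model = fit_oplsda(X, labels, n_orthogonal=0, scale="none", compute_q2=False)
        y, _ = encode_labels(labels)
        w, t, p, c = nipals_pls1(X, y)
        sign = np.sign(w @ model.predictive_weights)
        np.testing.assert_allclose(model.predictive_weights, sign * w, atol=1e-8)
        np.testing.assert_allclose(model.predictive_scores, sign * t, atol=1e-8)
        np.testing.assert_allclose(model.predictive_loadings, sign * p, atol=1e-8)

    def test_zero_orthogonal_matches_sklearn_pls(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 7))
        labels = two_group_labels(5)
        y, _ = encode_labels(labels)
        model = fit_oplsda(X, labels, n_orthogonal=0, scale="none", compute_q2=False)
        ref = sklearn_pls.PLSRegression(n_components=1, scale=False).fit(X, y)
        ref_t = ref.x_scores_[:, 0]
        sign = np.sign(ref_t @ model.predictive_scores)
        np.testing.assert_allclose(
            model.predictive_scores / np.linalg.norm(model.predictive_scores),
            sign * ref_t / np.linalg.norm(ref_t),
            atol=1e-8,
        )

    def test_predictive_orthogonal_to_orthogonal_scores(self, benchmark_model):
        t = benchmark_model.predictive_scores
        for a in range(benchmark_model.n_orthogonal):
            assert abs(t @ benchmark_model.orthogonal_scores[:, a]) < 1e-8 * (
                np.linalg.norm(t) * np.linalg.norm(benchmark_model.orthogonal_scores[:, a])
            )

    def test_filtered_x_free_of_orthogonal_weights(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(12, 9))
        labels = two_group_labels(6)
        model = fit_oplsda(X, labels, n_orthogonal=2, scale="none", compute_q2=False)
        Xs = model.X_scaled.copy()
        for a in range(model.n_orthogonal):
            t_o = Xs @ model.orthogonal_weights[:, a]
            Xs = Xs - np.outer(t_o, model.orthogonal_loadings[:, a])
        # no remaining systematic variation along the orthogonal weights
        for a in range(model.n_orthogonal):
            assert np.linalg.norm(Xs @ model.orthogonal_weights[:, a]) < 1e-8

    def test_r2y_bounded_and_reported(self, benchmark_model):
        assert benchmark_model.R2Y <= 1.0
        assert 0.0 <= benchmark_model.R2X <= 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(DataError):
            fit_oplsda(X, np.array(["viable"] * 6), compute_q2=False)

    def test_tiny_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        labels = np.array(["a", "a", "a", "a", "b", "b"])
        with pytest.raises(DataError, match=">= 3"):
            fit_oplsda(X, labels, compute_q2=False)


class TestQ2:
    def test_no_signal_gives_no_predictive_power(self):
        # permuted labels on structureless data: mean LOO Q2 near or below 0
        rng = np.random.default_rng(100)
        q2s = []
        for _ in range(50):
            X = rng.normal(size=(12, 20))
            labels = rng.permutation(two_group_labels(6))
            q2s.append(fit_oplsda(X, labels, n_orthogonal=1, scale="none").Q2)
        assert np.mean(q2s) < 0.1

    def test_strong_effect_cohort_exceeds_validity_threshold(self, benchmark_model):
        # Q2 > 0.4 is the field's validity bar for biological classification
        assert benchmark_model.Q2 > 0.4

    def test_q2_degrades_monotonically_with_effect_size(self):
        import dataclasses

        q2 = {}
        for effect in (2.0, 1.0, 0.5, 0.0):
            cfg = om.SyntheticConfig(
                n_patients=2, regions=("necrotic", "viable"), sites_per_region=5,
                n_background_compounds=40, n_discriminative_compounds=8,
                effect_size=effect, missing_rate=0.0, seed=21,
            )
            spectra, _, _ = om.generate_cohort(cfg)
            res = om.preprocess(spectra)
            q2[effect] = fit_oplsda(res.tic, res.tic.regions(), 1, "pareto").Q2
        assert q2[2.0] > q2[1.0] > q2[0.0]
        assert q2[2.0] > q2[0.5] > q2[0.0]


class TestVip:
    def test_mean_square_is_one(self, benchmark_model):
        vip = benchmark_model.vip
        assert np.sum(vip**2) == pytest.approx(vip.size, abs=1e-8)

    def test_single_informative_feature_attains_max(self):
        rng = np.random.default_rng(31)
        n = 20
        labels = two_group_labels(10)
        y, _ = encode_labels(labels)
        X = rng.normal(size=(n, 15)) * 0.3
        X[:, 4] += 3 * y
        model = fit_oplsda(X, labels, n_orthogonal=0, scale="none", compute_q2=False)
        assert int(np.argmax(model.vip)) == 4

    def test_identical_copies_share_vip_one(self):
        rng = np.random.default_rng(32)
        labels = two_group_labels(6)
        y, _ = encode_labels(labels)
        signal = y + 0.1 * rng.normal(size=12)
        X = np.tile(signal[:, None], (1, 7))
        model = fit_oplsda(X, labels, n_orthogonal=0, scale="none", compute_q2=False)
        np.testing.assert_allclose(model.vip, 1.0, atol=1e-8)

    def test_spiked_feature_recovery_above_90_percent(
        self, benchmark_cohort, benchmark_preprocessed, benchmark_model
    ):
        _, _, truth, _ = benchmark_cohort
        cent = benchmark_preprocessed.tic.feature_centroids
        spiked = truth.spiked_mzs()
        hits = 0
        for mz in spiked:
            j = int(np.argmin(np.abs(cent - mz)))
            if abs(cent[j] - mz) / mz * 1e6 < 5 and benchmark_model.vip[j] >= 1.0:
                hits += 1
        assert hits / len(spiked) >= 0.90


class TestSplot:
    def test_feature_equal_to_scores_has_unit_correlation(self):
        rng = np.random.default_rng(41)
        labels = two_group_labels(8)
        y, _ = encode_labels(labels)
        X = rng.normal(size=(16, 6))
        model = fit_oplsda(X, labels, n_orthogonal=0, scale="none", compute_q2=False)
        t = model.predictive_scores
        X2 = np.column_stack([X, X @ model.predictive_weights])  # last col == t
        model2 = fit_oplsda(X2, labels, n_orthogonal=0, scale="none", compute_q2=False)
        # the feature proportional to +-t reaches |correlation| ~ 1
        assert abs(model2.splot_corr[-1]) == pytest.approx(1.0, abs=1e-6)

    def test_agreement_with_closed_form(self):
        rng = np.random.default_rng(42)
        labels = two_group_labels(7)
        X = rng.normal(size=(14, 9))
        model = fit_oplsda(X, labels, n_orthogonal=1, scale="none", compute_q2=False)
        t = model.predictive_scores
        Xs = model.X_scaled
        for j in range(9):
            cov = np.cov(t, Xs[:, j], ddof=1)[0, 1]
            corr = np.corrcoef(t, Xs[:, j])[0, 1]
            assert model.splot_cov[j] == pytest.approx(cov, abs=1e-10)
            assert model.splot_corr[j] == pytest.approx(corr, abs=1e-10)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(43)
        labels = two_group_labels(6)
        y, _ = encode_labels(labels)
        base = y + 0.05 * rng.normal(size=12)
        X = np.column_stack([base, -base, rng.normal(size=12)])
        model = fit_oplsda(X, labels, n_orthogonal=0, scale="none", compute_q2=False)
        assert model.splot_corr[0] == pytest.approx(-model.splot_corr[1], abs=1e-9)


class TestPermutation:
    def test_strong_separation_minimal_p(self, benchmark_preprocessed):
        tic = benchmark_preprocessed.tic
        null, observed, p = permutation_test(
            tic, tic.regions(), n_permutations=99, seed=5, n_orthogonal=1
        )
        assert p == pytest.approx(1 / 100)
        assert observed > null.max()

    def test_null_labels_calibrated(self):
        rng = np.random.default_rng(55)
        ok = 0
        for trial in range(20):
            X = rng.normal(size=(12, 15))
            labels = rng.permutation(two_group_labels(6))
            _, _, p = permutation_test(
                X, labels, n_permutations=49, seed=trial, scale="none"
            )
            ok += p > 0.05
        assert ok >= 18  # >= 90% of null runs non-significant

    def test_same_seed_identical_distribution(self, benchmark_preprocessed):
        tic = benchmark_preprocessed.tic
        a, _, _ = permutation_test(tic, tic.regions(), n_permutations=19, seed=9)
        b, _, _ = permutation_test(tic, tic.regions(), n_permutations=19, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((6, 2)), two_group_labels(3), n_permutations=0)
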