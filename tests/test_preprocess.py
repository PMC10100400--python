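"""Preprocessing chain: peak selection, alignment, imputation, scaling."""

import numpy as np
import pytest

import orbimet as om
from orbimet.containers import DataError, DepthProfileSpectrum, FeatureMatrix, SampleMeta
from orbimet.preprocess import (
    align_features,
    filter_missing,
    knn_impute,
    pareto_scale,
    remove_background,
    select_peaks,
    tic_normalize,
)


def spectrum(mz, intensity, region="viable", patient="P1", site=1):
    return DepthProfileSpectrum(mz, intensity, SampleMeta(patient, region, site))


def matrix_from(values, mask=None, centroids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    mask = np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    values = np.where(mask, np.nan, values)
    metas = [SampleMeta("P1", "viable", i + 1) for i in range(n)]
    return FeatureMatrix(
        [m.sample_id for m in metas], metas,
        centroids if centroids is not None else 100.0 + 10.0 * np.arange(p),
        values, mask,
    )


class TestSelectPeaks:
    def test_single_peak_always_retained(self):
        s = select_peaks(spectrum([100.0], [5.0]), 0.5)
        assert s.n_peaks == 1

    def test_forced_cutoff(self):
        s = select_peaks(spectrum([100.0, 200.0, 300.0], [1000.0, 5.0, 0.5]), 0.001)
        np.testing.assert_array_equal(s.intensity, [1000.0, 5.0])

    def test_matches_brute_force_on_random_spectrum(self):
        rng = np.random.default_rng(0)
        inten = rng.lognormal(3, 2, size=500)
        mz = np.sort(rng.uniform(75, 1125, size=500))
        s = select_peaks(spectrum(mz, inten), 0.001)
        assert s.n_peaks == int(np.sum(inten >= inten.max() * 0.001))

    def test_empty_spectrum_rejected(self):
        with pytest.raises(DataError):
            select_peaks(spectrum([], []))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_threshold_range_enforced(self, bad):
        with pytest.raises(ValueError):
            select_peaks(spectrum([100.0], [1.0]), bad)


class TestAlignFeatures:
    def test_identical_single_peaks_make_one_full_feature(self):
        specs = [spectrum([100.0], [1.0], site=i + 1) for i in range(2)]
        m = align_features(specs)
        assert m.n_features == 1
        assert m.feature_centroids[0] == pytest.approx(100.0)
        assert not m.missing_mask.any()

    def test_ppm_window_merge_and_split(self):
        # 200.0000 vs 200.0008 is 4.0 ppm -> merge; vs 200.0030 is 15 ppm -> split
        close = align_features(
            [spectrum([200.0], [1.0], site=1), spectrum([200.0008], [1.0], site=2)],
            window_ppm=5.0,
        )
        assert close.n_features == 1
        far = align_features(
            [spectrum([200.0], [1.0], site=1), spectrum([200.0030], [1.0], site=2)],
            window_ppm=5.0,
        )
        assert far.n_features == 2

    def test_well_separated_peaks_identity_partition(self):
        mz = np.linspace(100, 1000, 50)
        m = align_features([spectrum(mz, np.ones(50))])
        assert m.n_features == 50
        assert not m.missing_mask.any()

    def test_within_sample_peaks_in_window_are_summed(self):
        m = align_features([spectrum([200.0, 200.0004], [1.0, 2.0])], window_ppm=5.0)
        assert m.n_features == 1
        assert m.values[0, 0] == pytest.approx(3.0)

    def test_centroid_is_intensity_weighted(self):
        m = align_features([spectrum([200.0, 200.0004], [1.0, 3.0])], window_ppm=5.0)
        assert m.feature_centroids[0] == pytest.approx(200.0003)

    def test_realigning_centroids_is_fixed_point(self, benchmark_preprocessed):
        cent = benchmark_preprocessed.aligned.feature_centroids
        again = align_features([spectrum(cent, np.ones(cent.size))])
        assert again.n_features == cent.size

    def test_members_within_window_of_centroid(self, benchmark_cohort, benchmark_preprocessed):
        _, spectra, _, _ = benchmark_cohort
        cent = np.sort(benchmark_preprocessed.aligned.feature_centroids)
        for s in spectra[:10]:
            j = np.clip(np.searchsorted(cent, s.mz), 1, cent.size - 1)
            nearest = np.where(
                np.abs(s.mz - cent[j - 1]) < np.abs(s.mz - cent[j]), cent[j - 1], cent[j]
            )
            assert np.all(np.abs(s.mz - nearest) / nearest * 1e6 <= 5.0)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            align_features([spectrum([100.0], [1.0])], window_ppm=0.0)


class TestFilterMissing:
    def test_boundary_20_percent_retained_strictly_more_removed(self):
        mask = np.zeros((10, 2), dtype=bool)
        mask[:2, 0] = True  # 20% missing -> retained
        mask[:3, 1] = True  # 30% missing -> removed
        m = filter_missing(matrix_from(np.ones((10, 2)), mask))
        assert m.n_features == 1
        assert m.feature_centroids[0] == pytest.approx(100.0)

    def test_fully_observed_identity(self):
        m0 = matrix_from(np.arange(12.0).reshape(4, 3))
        m = filter_missing(m0)
        np.testing.assert_array_equal(m.values, m0.values)
        assert m.n_features == 3


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        m0 = matrix_from(np.arange(12.0).reshape(4, 3))
        m = knn_impute(m0)
        np.testing.assert_array_equal(m.values, m0.values)

    def test_k1_equals_brute_force_nearest_neighbour(self):
        values = np.array([[1.0, 10.0, 5.0], [1.1, 11.0, np.nan], [9.0, 50.0, 8.0]])
        mask = np.isnan(values)
        m = knn_impute(matrix_from(values, mask), k=1)
        # sample 1's nearest neighbour on jointly observed features is sample 0
        assert m.values[1, 2] == pytest.approx(5.0)
        assert not m.missing_mask.any()

    def test_imputed_within_donor_range(self, benchmark_preprocessed):
        filtered = benchmark_preprocessed.filtered
        imputed = benchmark_preprocessed.imputed
        for i, j in zip(*np.nonzero(filtered.missing_mask)):
            donors = filtered.values[~filtered.missing_mask[:, j], j]
            assert donors.min() <= imputed.values[i, j] <= donors.max()

    def test_observed_cells_unchanged(self, benchmark_preprocessed):
        filtered = benchmark_preprocessed.filtered
        imputed = benchmark_preprocessed.imputed
        obs = ~filtered.missing_mask
        np.testing.assert_array_equal(imputed.values[obs], filtered.values[obs])

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            knn_impute(matrix_from(np.ones((3, 2))), k=0)


class TestRemoveBackground:
    def test_empty_blacklist_identity(self):
        m = remove_background(matrix_from(np.ones((2, 3))))
        assert m.n_features == 3

    def test_exact_centroid_removed(self):
        m = remove_background(matrix_from(np.ones((2, 3))), blacklist=[110.0])
        assert m.n_features == 2
        assert 110.0 not in m.feature_centroids

    def test_entry_outside_tolerance_kept(self):
        # 10 ppm away at 5 ppm tolerance -> no removal
        centroid = 500.0
        m = remove_background(
            matrix_from(np.ones((2, 1)), centroids=[centroid]),
            blacklist=[centroid * (1 + 10e-6)],
            tolerance_ppm=5.0,
        )
        assert m.n_features == 1


class TestNormalizeAndScale:
    def test_single_feature_becomes_one(self):
        m = tic_normalize(matrix_from([[5.0], [2.0]]))
        np.testing.assert_allclose(m.values, 1.0)

    def test_hand_example(self):
        m = tic_normalize(matrix_from([[1.0, 3.0]]))
        np.testing.assert_allclose(m.values, [[0.25, 0.75]])

    def test_row_sums_one_and_idempotent(self):
        rng = np.random.default_rng(1)
        m = tic_normalize(matrix_from(rng.lognormal(size=(6, 9))))
        np.testing.assert_allclose(m.values.sum(axis=1), 1.0, atol=1e-12)
        again = tic_normalize(m)
        np.testing.assert_allclose(again.values, m.values, atol=1e-12)

    def test_zero_total_sample_named(self):
        with pytest.raises(DataError, match="P1_viable_s1"):
            tic_normalize(matrix_from([[0.0, 0.0], [1.0, 2.0]]))

    def test_missing_values_rejected(self):
        m = matrix_from([[1.0, np.nan]], mask=[[False, True]])
        with pytest.raises(DataError):
            tic_normalize(m)

    def test_pareto_hand_example(self):
        m = pareto_scale(matrix_from([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(m.values.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_pareto_variance_identity(self):
        # a column with pre-scaling sd 4 has post-scaling variance 4
        col = np.array([-4.0, 0.0, 4.0])  # sd (n-1 denominator) = 4
        m = pareto_scale(matrix_from(col[:, None]))
        assert m.values[:, 0].var(ddof=1) == pytest.approx(4.0, abs=1e-9)
        assert m.values[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_zeroed_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="orbimet.preprocess"):
            m = pareto_scale(matrix_from([[2.0, 1.0], [2.0, 3.0]]))
        np.testing.assert_array_equal(m.values[:, 0], [0.0, 0.0])
        assert any("constant" in r.message for r in caplog.records)

    def test_double_pareto_forbidden(self):
        m = pareto_scale(matrix_from([[1.0], [2.0], [3.0]]))
        with pytest.raises(DataError, match="already"):
            pareto_scale(m)


def test_chain_order_recorded(benchmark_preprocessed):
    log = benchmark_preprocessed.scaled.transform_log
    names = [entry.split("(")[0] for entry in log]
    assert names == [
        "align_features",
        "filter_missing",
        "knn_impute",
        "remove_background",
        "tic_normalize",
        "pareto_scale",
    ]


def test_filter_missing_bound_holds(benchmark_preprocessed):
    assert (benchmark_preprocessed.filtered.missing_fraction() <= 0.20 + 1e-12).all()
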