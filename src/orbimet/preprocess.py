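"""From per-site peak lists to an analysis-ready feature matrix.

The chain and its defaults follow the depth-profile workflow this package
reproduces, in this fixed order:

    select_peaks (0.1% of base peak)
    -> align_features (5 ppm window)
    -> filter_missing (drop features >20% missing)
    -> knn_impute (k = 5)
    -> remove_background (optional blacklist)
    -> tic_normalize
    -> pareto_scale

Every step appends to the matrix's ``transform_log`` so the history is
auditable and repeat applications of non-idempotent steps are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import DataError, DepthProfileSpectrum, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "select_peaks",
    "align_features",
    "filter_missing",
    "knn_impute",
    "remove_background",
    "tic_normalize",
    "pareto_scale",
    "preprocess",
    "PreprocessResult",
]


def select_peaks(
    spectrum: DepthProfileSpectrum, threshold_fraction: float = 0.001
) -> DepthProfileSpectrum:
    """Keep peaks with intensity >= threshold_fraction x base-peak intensity."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if spectrum.n_peaks == 0:
        raise DataError("cannot select peaks from an empty spectrum")
    cutoff = threshold_fraction * spectrum.base_peak_intensity()
    keep = spectrum.intensity >= cutoff
    return DepthProfileSpectrum(spectrum.mz[keep], spectrum.intensity[keep], spectrum.meta)


def align_features(
    spectra: list[DepthProfileSpectrum], window_ppm: float = 5.0
) -> FeatureMatrix:
    """Cluster pooled peaks into m/z features within a ppm window.

    All peaks from all spectra are pooled, sorted ascending, and swept left
    to right; a peak joins the current cluster while its ppm distance to the
    cluster's running intensity-weighted centroid is within ``window_ppm``,
    otherwise it starts a new cluster.  A sample's value for a feature is
    the *sum* of its peaks in that cluster; samples contributing no peak to
    a cluster are recorded as missing.
    """
    if window_ppm <= 0:
        raise ValueError("window_ppm must be > 0")
    if not spectra:
        raise DataError("no spectra to align")
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    sample = np.concatenate(
        [np.full(s.n_peaks, i, dtype=int) for i, s in enumerate(spectra)]
    )
    order = np.argsort(mz, kind="stable")
    mz, inten, sample = mz[order], inten[order], sample[order]

    cluster_id = np.empty(mz.size, dtype=int)
    centroids: list[float] = []
    w_sum = 0.0
    wm_sum = 0.0
    current = -1
    for i in range(mz.size):
        if current >= 0:
            centroid = wm_sum / w_sum
            if abs(mz[i] - centroid) / centroid * 1e6 <= window_ppm:
                cluster_id[i] = current
                w_sum += inten[i]
                wm_sum += inten[i] * mz[i]
                continue
            centroids.append(wm_sum / w_sum)
        current += 1
        cluster_id[i] = current
        w_sum, wm_sum = inten[i], inten[i] * mz[i]
    if mz.size:
        centroids.append(wm_sum / w_sum)

    n, p = len(spectra), len(centroids)
    values = np.zeros((n, p))
    seen = np.zeros((n, p), dtype=bool)
    np.add.at(values, (sample, cluster_id), inten)
    seen[sample, cluster_id] = True
    values[~seen] = np.nan

    matrix = FeatureMatrix(
        sample_ids=[s.meta.sample_id for s in spectra],
        sample_meta=[s.meta for s in spectra],
        feature_centroids=np.array(centroids),
        values=values,
        missing_mask=~seen,
        transform_log=[f"align_features(window_ppm={window_ppm})"],
    )
    matrix.validate()
    logger.info("aligned %d spectra into %d features", n, p)
    return matrix


def filter_missing(
    matrix: FeatureMatrix, max_missing_fraction: float = 0.20
) -> FeatureMatrix:
    """Drop features whose missing fraction exceeds the cutoff (strict >)."""
    frac = matrix.missing_fraction()
    keep = np.flatnonzero(frac <= max_missing_fraction)
    dropped = matrix.n_features - keep.size
    if dropped:
        logger.info("filter_missing dropped %d/%d features", dropped, matrix.n_features)
    if keep.size == 0:
        logger.warning("filter_missing removed every feature")
    return matrix.take_features(
        keep, f"filter_missing(max_missing_fraction={max_missing_fraction})"
    )


def _standardized(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-feature z-scores over observed cells (NaN where missing)."""
    z = np.where(mask, np.nan, values)
    mean = np.nanmean(z, axis=0)
    sd = np.nanstd(z, axis=0, ddof=1)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    return (z - mean) / sd


def knn_impute(matrix: FeatureMatrix, k: int = 5) -> FeatureMatrix:
    """Fill missing cells with the mean of the k nearest samples' values.

    Distance between two samples is the root-mean-square difference of
    per-feature standardized values over the features observed in both;
    ties break by sample order.  If a feature has fewer than k observing
    donors, all available donors are used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not matrix.missing_mask.any():
        return matrix.with_values(matrix.values.copy(), f"knn_impute(k={k})")
    z = _standardized(matrix.values, matrix.missing_mask)
    n = matrix.n_samples
    # pairwise RMS distance over jointly observed features
    dist = np.full((n, n), np.inf)
    for i in range(n):
        diff = z[i] - z  # (n, p) with NaN where either is missing
        shared = np.isfinite(diff)
        counts = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.sqrt(np.nansum(diff**2, axis=1) / np.maximum(counts, 1))
        d[counts == 0] = np.inf
        dist[i] = d
    np.fill_diagonal(dist, np.inf)

    values = matrix.values.copy()
    for i, j in zip(*np.nonzero(matrix.missing_mask)):
        donors = np.flatnonzero(~matrix.missing_mask[:, j])
        if donors.size == 0:
            raise DataError(
                f"feature at m/z {matrix.feature_centroids[j]:.4f} has no observed "
                "values to impute from"
            )
        # stable sort on distance keeps sample order as the tie-break
        nearest = donors[np.argsort(dist[i, donors], kind="stable")][:k]
        values[i, j] = matrix.values[nearest, j].mean()
    out = matrix.with_values(
        values, f"knn_impute(k={k})", missing_mask=np.zeros_like(matrix.missing_mask)
    )
    out.validate()
    return out


def remove_background(
    matrix: FeatureMatrix,
    blacklist: list[float] | np.ndarray = (),
    tolerance_ppm: float = 5.0,
) -> FeatureMatrix:
    """Drop features whose centroid matches a blacklisted m/z within tolerance."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    blacklist = np.asarray(blacklist, dtype=float)
    if blacklist.size == 0:
        return matrix.take_features(
            np.arange(matrix.n_features), "remove_background(n=0)"
        )
    cent = matrix.feature_centroids
    hit = np.zeros(matrix.n_features, dtype=bool)
    for b in blacklist:
        hit |= np.abs(cent - b) / b * 1e6 <= tolerance_ppm
    if hit.any():
        logger.info(
            "remove_background dropped features at m/z %s", cent[hit].round(4).tolist()
        )
    return matrix.take_features(
        np.flatnonzero(~hit), f"remove_background(n={int(hit.sum())})"
    )


def tic_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample's intensities by its total ion count (row sum)."""
    if matrix.missing_mask.any():
        raise DataError("tic_normalize requires an imputed (no-missing) matrix")
    totals = matrix.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise DataError(
            f"zero total ion count for sample(s) {[matrix.sample_ids[i] for i in zero]}"
        )
    return matrix.with_values(matrix.values / totals[:, None], "tic_normalize")


def pareto_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Mean-centre each feature and divide by the square root of its SD.

    Pareto scaling is intermediate between no scaling and unit-variance
    scaling: a column with pre-scaling standard deviation s ends with
    variance s.  Constant columns become all zeros (with a warning).
    Applying the transform twice is refused via the transform log.
    """
    if matrix.missing_mask.any():
        raise DataError("pareto_scale requires an imputed (no-missing) matrix")
    if any(entry.startswith("pareto_scale") for entry in matrix.transform_log):
        raise DataError("pareto_scale has already been applied to this matrix")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "pareto_scale: %d constant feature(s) set to zero", int(constant.sum())
        )
    scale = np.where(constant, 1.0, np.sqrt(sd))
    values = (matrix.values - mean) / scale
    values[:, constant] = 0.0
    return matrix.with_values(values, "pareto_scale")


@dataclass
class PreprocessResult:
    """Checkpoints of the preprocessing chain.

    ``tic`` (TIC-normalized, unscaled) feeds univariate statistics and the
    chemometric engine (which Pareto-scales within cross-validation folds);
    ``scaled`` is the Pareto-scaled matrix for direct inspection.
    """

    aligned: FeatureMatrix
    filtered: FeatureMatrix
    imputed: FeatureMatrix
    tic: FeatureMatrix
    scaled: FeatureMatrix


def preprocess(
    spectra: list[DepthProfileSpectrum],
    threshold_fraction: float = 0.001,
    window_ppm: float = 5.0,
    max_missing_fraction: float = 0.20,
    k: int = 5,
    background_blacklist: list[float] | np.ndarray = (),
    background_tolerance_ppm: float = 5.0,
) -> PreprocessResult:
    """Run the full chain in its fixed order and return every checkpoint."""
    selected = [select_peaks(s, threshold_fraction) for s in spectra]
    aligned = align_features(selected, window_ppm)
    filtered = filter_missing(aligned, max_missing_fraction)
    imputed = knn_impute(filtered, k)
    cleaned = remove_background(imputed, background_blacklist, background_tolerance_ppm)
    tic = tic_normalize(cleaned)
    scaled = pareto_scale(tic)
    return PreprocessResult(aligned, filtered, imputed, tic, scaled)
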