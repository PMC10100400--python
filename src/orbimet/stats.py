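"""Univariate feature statistics and the two feature-selection predicates.

Discriminative ions: VIP >= 1 in the OPLS-DA model AND FDR-adjusted
q < 0.05 from a pooled-variance Student's t-test.  Ubiquitous ions
(equal abundance across the two compared regions): VIP >= 1 AND raw
p > 0.05 — the predicate as printed in the source workflow; a documented
alternative (VIP < 1, i.e. low multivariate importance) is selectable.
Tests run on TIC-normalized (not Pareto-scaled) intensities.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import DataError, FeatureMatrix
from .chemometrics import OplsdaModel

logger = logging.getLogger(__name__)

__all__ = [
    "student_t_tests",
    "benjamini_hochberg",
    "select_discriminative",
    "select_ubiquitous",
    "feature_stats_table",
]


def student_t_tests(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    welch: bool = False,
    group_order: tuple[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided per-feature t-tests between two groups.

    The default is the pooled-variance Student's t with n1+n2-2 degrees of
    freedom, computed as first group minus second (``group_order``, or the
    order of first appearance in ``labels``); ``welch=True`` switches to
    unequal-variance Welch.  Features with zero pooled variance get t = 0,
    p = 1 with a warning.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if isinstance(matrix, FeatureMatrix) and matrix.missing_mask.any():
        raise DataError("t-tests require an imputed matrix")
    labels = np.asarray(labels)
    classes = list(group_order) if group_order else list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2 or set(classes) != set(labels.tolist()):
        raise DataError(f"exactly two groups required, got {classes}")
    a = X[labels == classes[0]]
    b = X[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=not welch)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning(
            "%d feature(s) with zero pooled variance: t=0, p=1", int(degenerate.sum())
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return np.asarray(t, float), np.asarray(p, float)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up FDR-adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def select_discriminative(
    vip: np.ndarray,
    q: np.ndarray,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """Flag features with VIP >= threshold and FDR-adjusted q < alpha."""
    vip, q = np.asarray(vip, float), np.asarray(q, float)
    if vip.shape != q.shape:
        raise ValueError(f"length mismatch: vip {vip.shape} vs q {q.shape}")
    return (vip >= vip_threshold) & (q < alpha)


def select_ubiquitous(
    vip: np.ndarray,
    p: np.ndarray,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    predicate: str = "high_vip",
) -> np.ndarray:
    """Flag features of equal abundance between the compared regions.

    ``predicate="high_vip"`` is the printed rule: VIP >= threshold AND
    p > alpha.  ``predicate="low_vip"`` is the alternative reading
    (VIP < threshold AND p > alpha) for features unimportant to the class
    separation; the default follows the printed rule verbatim.
    """
    vip, p = np.asarray(vip, float), np.asarray(p, float)
    if vip.shape != p.shape:
        raise ValueError(f"length mismatch: vip {vip.shape} vs p {p.shape}")
    if predicate == "high_vip":
        return (vip >= vip_threshold) & (p > alpha)
    if predicate == "low_vip":
        return (vip < vip_threshold) & (p > alpha)
    raise ValueError("predicate must be 'high_vip' or 'low_vip'")


def feature_stats_table(
    tic_matrix: FeatureMatrix,
    model: OplsdaModel,
    labels: np.ndarray,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    welch: bool = False,
    ubiquitous_predicate: str = "high_vip",
) -> pd.DataFrame:
    """Per-feature results table: group means, t, p, q, VIP and both flags."""
    labels = np.asarray(labels)
    t, p = student_t_tests(tic_matrix, labels, welch=welch)
    q = benjamini_hochberg(p)
    vip = model.vip
    if vip.size != tic_matrix.n_features:
        raise DataError("model and matrix disagree on the number of features")
    table = pd.DataFrame({"feature_mz": tic_matrix.feature_centroids})
    for cls in dict.fromkeys(labels.tolist()):
        table[f"mean_{cls}"] = tic_matrix.values[labels == cls].mean(axis=0)
    table["t_statistic"] = t
    table["p_value"] = p
    table["q_value"] = q
    table["vip"] = vip
    table["discriminative"] = select_discriminative(vip, q, vip_threshold, alpha)
    table["ubiquitous"] = select_ubiquitous(
        vip, p, vip_threshold, alpha, ubiquitous_predicate
    )
    return table
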