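"""PCA and a from-scratch two-class OPLS-DA engine.

OPLS-DA separates class-predictive variation from class-orthogonal
variation before fitting a single predictive PLS component.  The algorithm
is the orthogonal-signal-correction scheme of Trygg-Wold OPLS applied to a
centred +/-1 class dummy y:

1. ``w = X'y / ||X'y||`` — the PLS weight vector;
2. for each orthogonal component: ``t = Xw``, ``p = X't/t't``,
   ``w_o ∝ p − (w'p)w`` (the part of the loading orthogonal to the
   predictive weight), ``t_o = Xw_o``, ``p_o = X't_o/t_o't_o``, and X is
   deflated by ``t_o p_o'``;
3. the predictive component ``t = X_filtered w``, ``p``, and the inner
   regression coefficient ``c = y't/t't`` are fitted on the filtered X.

Q² uses leave-one-out cross-validation: each held-out sample is predicted
by a model refit from scratch — including centring and (optionally) Pareto
scaling statistics — on the remaining samples.  The permutation test refits
the whole cross-validated pipeline under randomly permuted class labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import DataError, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PcaModel",
    "OplsdaModel",
    "fit_pca",
    "fit_oplsda",
    "vip_scores",
    "s_plot",
    "permutation_test",
    "encode_labels",
]

_EPS = 1e-12


def _as_array(matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        if matrix.missing_mask.any():
            raise DataError("chemometric models require an imputed matrix")
        return np.asarray(matrix.values, dtype=float)
    return np.asarray(matrix, dtype=float)


def encode_labels(labels: np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    """Encode a two-class label vector as +1/-1 (first-appearing class = +1)."""
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    if len(classes) != 2:
        raise DataError(f"exactly two classes required, got {classes}")
    y = np.where(labels == classes[0], 1.0, -1.0)
    return y, (classes[0], classes[1])


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: np.ndarray  # (n, a)
    loadings: np.ndarray  # (p, a)
    mean: np.ndarray
    explained_R2X: np.ndarray  # cumulative, length a
    Q2: float


def fit_pca(
    matrix: FeatureMatrix | np.ndarray,
    n_components: int = 2,
    cv_folds: int = 7,
) -> PcaModel:
    """Principal component analysis by SVD of the column-centred matrix.

    ``Q2`` is computed by venetian-blind row exclusion: rows are assigned to
    ``cv_folds`` folds in round-robin order, each fold is reconstructed from
    a model fitted to the remaining rows, and Q2 = 1 - PRESS/SS.
    """
    X = _as_array(matrix)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        warnings.warn(
            f"n_components reduced from {n_components} to rank bound {max_rank}"
        )
        n_components = max_rank
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    total = float(np.sum(s**2))
    explained = np.cumsum(s[:n_components] ** 2) / total if total > 0 else np.ones(n_components)

    folds = min(cv_folds, n)
    press = 0.0
    ss = 0.0
    for f in range(folds):
        test = np.arange(n) % folds == f
        if test.all() or not test.any():
            continue
        mu = X[~test].mean(axis=0)
        _, _, Vt_f = np.linalg.svd(X[~test] - mu, full_matrices=False)
        V = Vt_f[: min(n_components, Vt_f.shape[0])].T
        resid = (X[test] - mu) - (X[test] - mu) @ V @ V.T
        press += float(np.sum(resid**2))
        ss += float(np.sum((X[test] - mu) ** 2))
    q2 = 1.0 - press / ss if ss > 0 else 0.0
    return PcaModel(scores, loadings, mean, explained, q2)


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsdaModel:
    """A fitted two-class OPLS-DA model (one predictive component)."""

    classes: tuple[str, str]
    predictive_scores: np.ndarray  # t, (n,)
    predictive_loadings: np.ndarray  # p, (p,)
    predictive_weights: np.ndarray  # w (unit norm), (p,)
    inner_coefficient: float  # c: y ≈ t * c
    orthogonal_scores: np.ndarray  # (n, a_o)
    orthogonal_loadings: np.ndarray  # (p, a_o)
    orthogonal_weights: np.ndarray  # (p, a_o)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    scale: str
    R2X: float
    R2Y: float
    Q2: float
    vip: np.ndarray = field(default=None)
    splot_cov: np.ndarray = field(default=None)
    splot_corr: np.ndarray = field(default=None)
    X_scaled: np.ndarray = field(default=None, repr=False)
    permutation_Q2: np.ndarray | None = field(default=None, repr=False)
    permutation_p: float | None = None

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_scores.shape[1]

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new samples."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean) / self.x_scale
        T_o = np.zeros((Xs.shape[0], self.n_orthogonal))
        for a in range(self.n_orthogonal):
            w_o = self.orthogonal_weights[:, a]
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, self.orthogonal_loadings[:, a])
            T_o[:, a] = t_o
        return Xs @ self.predictive_weights, T_o

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction on the +/-1 scale."""
        t, _ = self.transform(X)
        return t * self.inner_coefficient + self.y_mean

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        yhat = self.predict(X)
        return np.where(yhat >= 0, self.classes[0], self.classes[1])


def _scaling(X: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scale == "none":
        return mean, np.ones(X.shape[1])
    if scale == "pareto":
        sd = X.std(axis=0, ddof=1)
        s = np.sqrt(sd)
        s[s < _EPS] = 1.0
        return mean, s
    if scale == "uv":
        sd = X.std(axis=0, ddof=1)
        sd[sd < _EPS] = 1.0
        return mean, sd
    raise ValueError(f"unknown scale {scale!r}; use 'none', 'pareto' or 'uv'")


def _fit_core(
    Xs: np.ndarray, yc: np.ndarray, n_orthogonal: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OPLS core on already centred/scaled data; returns component set."""
    n, p = Xs.shape
    w = Xs.T @ yc
    nw = np.linalg.norm(w)
    if nw < _EPS:
        raise DataError("X carries no covariance with the class labels")
    w = w / nw
    Xf = Xs.copy()
    W_o = np.zeros((p, n_orthogonal))
    P_o = np.zeros((p, n_orthogonal))
    T_o = np.zeros((n, n_orthogonal))
    kept = 0
    for _ in range(n_orthogonal):
        t = Xf @ w
        pp = Xf.T @ t / max(t @ t, _EPS)
        w_o = pp - (w @ pp) * w
        norm_wo = np.linalg.norm(w_o)
        if norm_wo < 1e-10:
            break  # no remaining y-orthogonal systematic variation
        w_o /= norm_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / max(t_o @ t_o, _EPS)
        Xf = Xf - np.outer(t_o, p_o)
        W_o[:, kept], P_o[:, kept], T_o[:, kept] = w_o, p_o, t_o
        kept += 1
    W_o, P_o, T_o = W_o[:, :kept], P_o[:, :kept], T_o[:, :kept]
    t = Xf @ w
    p_vec = Xf.T @ t / max(t @ t, _EPS)
    c = float(yc @ t / max(t @ t, _EPS))
    return w, t, c, p_vec, W_o, P_o, T_o


def _predict_one(
    x: np.ndarray,
    w: np.ndarray,
    c: float,
    W_o: np.ndarray,
    P_o: np.ndarray,
    mean: np.ndarray,
    scale_vec: np.ndarray,
    y_mean: float,
) -> float:
    xs = (x - mean) / scale_vec
    for a in range(W_o.shape[1]):
        xs = xs - (xs @ W_o[:, a]) * P_o[:, a]
    return float(xs @ w) * c + y_mean


def fit_oplsda(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    n_orthogonal: int = 1,
    scale: str = "pareto",
    compute_q2: bool = True,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model with one predictive component.

    ``scale`` controls the within-model column treatment: ``"pareto"``
    (centre + Pareto, refit inside every cross-validation fold) for a
    TIC-normalized input matrix, or ``"none"`` (centre only) if the input
    is already scaled.  Each class must have at least 3 samples.
    """
    X = _as_array(matrix)
    y01, classes = encode_labels(labels)
    counts = [(y01 == 1).sum(), (y01 == -1).sum()]
    if min(counts) < 3:
        raise DataError(f"each class needs >= 3 samples, got {counts}")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")

    mean, scale_vec = _scaling(X, scale)
    Xs = (X - mean) / scale_vec
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    w, t, c, p_vec, W_o, P_o, T_o = _fit_core(Xs, yc, n_orthogonal)

    ssx = float(np.sum(Xs**2))
    ssy = float(np.sum(yc**2))
    modelled_x = float(np.sum(np.outer(t, p_vec) ** 2)) + float(
        np.sum((T_o @ P_o.T) ** 2)
    )
    r2x = modelled_x / ssx if ssx > 0 else 0.0
    r2y = 1.0 - float(np.sum((yc - t * c) ** 2)) / ssy

    q2 = np.nan
    if compute_q2:
        press = 0.0
        n = X.shape[0]
        for i in range(n):
            keep = np.arange(n) != i
            m_i, s_i = _scaling(X[keep], scale)
            yk = y01[keep]
            ym = float(yk.mean())
            try:
                w_i, _, c_i, _, Wo_i, Po_i, _ = _fit_core(
                    (X[keep] - m_i) / s_i, yk - ym, n_orthogonal
                )
            except DataError:
                press += (y01[i] - ym) ** 2
                continue
            yhat = _predict_one(X[i], w_i, c_i, Wo_i, Po_i, m_i, s_i, ym)
            press += (y01[i] - yhat) ** 2
        q2 = 1.0 - press / ssy

    model = OplsdaModel(
        classes=classes,
        predictive_scores=t,
        predictive_loadings=p_vec,
        predictive_weights=w,
        inner_coefficient=c,
        orthogonal_scores=T_o,
        orthogonal_loadings=P_o,
        orthogonal_weights=W_o,
        x_mean=mean,
        x_scale=scale_vec,
        y_mean=y_mean,
        scale=scale,
        R2X=r2x,
        R2Y=r2y,
        Q2=float(q2),
        X_scaled=Xs,
    )
    model.vip = vip_scores(model)
    model.splot_cov, model.splot_corr = s_plot(model)
    return model


def vip_scores(model: OplsdaModel) -> np.ndarray:
    """Variable importance in projection over the predictive component.

    With a single predictive component the VIP of feature j reduces to
    sqrt(J) * |w_j| / ||w||, so the mean squared VIP is exactly 1.
    """
    w = model.predictive_weights
    J = w.size
    return np.sqrt(J) * np.abs(w) / np.linalg.norm(w)


def s_plot(model: OplsdaModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature covariance and correlation with the predictive scores.

    Computed against the centred/scaled data matrix the model was fitted on
    (before orthogonal deflation), with the n-1 denominator.  Zero-variance
    features get correlation 0 with a warning.
    """
    t = model.predictive_scores
    Xs = model.X_scaled
    n = t.size
    tc = t - t.mean()
    cov = Xs.T @ tc / (n - 1)
    sx = Xs.std(axis=0, ddof=1)
    st = t.std(ddof=1)
    zero = sx < _EPS
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s): correlation set to 0")
    denom = np.where(zero, 1.0, sx * st)
    corr = np.where(zero, 0.0, cov / denom)
    return cov, np.clip(corr, -1.0, 1.0)


def permutation_test(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    n_orthogonal: int = 1,
    scale: str = "pareto",
) -> tuple[np.ndarray, float, float]:
    """Compare the observed cross-validated Q2 with its permutation null.

    Returns ``(permuted_Q2, observed_Q2, p)`` with the add-one empirical
    p-value p = (1 + #{Q2_perm >= Q2_obs}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = _as_array(matrix)
    labels = np.asarray(labels)
    observed = fit_oplsda(X, labels, n_orthogonal, scale).Q2
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        try:
            null[b] = fit_oplsda(X, perm, n_orthogonal, scale).Q2
        except DataError:
            null[b] = -np.inf
    p = (1 + int(np.sum(null >= observed))) / (n_permutations + 1)
    return null, observed, p
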