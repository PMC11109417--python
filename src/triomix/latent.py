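"""Latent-variable models and VIP-based marker fusion.

PCA by singular value decomposition; two-class PLS-DA via NIPALS PLS1 on a
{0,1}-coded response; variable importance in projection (VIP); stratified
cross-validation metrics (RMSE, R², Q²); training-fit ROC/AUROC; and the
fusion rule that calls a feature a group marker when its VIP clears a
threshold *and* its univariate q-value is significant, with the fold-change
sign assigning the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .core_io import ValidationError

logger = logging.getLogger("triomix")


def _fix_signs(loadings: np.ndarray, *aligned: np.ndarray):
    """Flip component signs so each loading's largest-|entry| is positive."""
    flips = np.ones(loadings.shape[1])
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            flips[a] = -1.0
    out = [loadings * flips] + [m * flips for m in aligned]
    return out[0] if not aligned else tuple(out)


@dataclass
class PCAModel:
    scores: np.ndarray            # samples x A
    loadings: np.ndarray          # features x A, orthonormal columns
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca(X: np.ndarray, n_comp: int = 2) -> PCAModel:
    """Principal component analysis of a samples-by-features matrix.

    Columns are centered internally; scores/loadings come from the SVD of
    the centered matrix, with signs fixed so the largest-magnitude loading
    entry of each component is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_comp > min(n - 1, p):
        raise ValidationError(f"n_comp={n_comp} exceeds min(n-1, p)={min(n - 1, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not Xc.any():
        raise ValidationError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    ratio = var / var.sum()
    loadings, scores = _fix_signs(vt[:n_comp].T, u[:, :n_comp] * s[:n_comp])
    return PCAModel(scores, loadings, ratio[:n_comp], mean)


@dataclass
class PLSDAModel:
    """NIPALS PLS1 fit of a {0,1}-coded class response.

    Stores per-component X-weights (unit norm), X-scores, X-loadings and
    y-loadings, plus the fitted regression for prediction.
    """

    weights: np.ndarray       # features x A
    scores: np.ndarray        # samples x A
    x_loadings: np.ndarray    # features x A
    y_loadings: np.ndarray    # A
    coef: np.ndarray          # features (regression vector on centered X)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    classes: tuple            # (negative/0 class, positive/1 class)
    n_comp: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) / self.x_scale @ self.coef + self.y_mean


def encode_labels(labels, positive: str = "UC") -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError(f"expected two classes, found {list(classes)}")
    matches = [c for c in classes if c == positive]
    pos = matches[0] if matches else classes[1]
    neg = classes[0] if pos == classes[1] else classes[1]
    return (labels == pos).astype(float), (neg, pos)


def plsda(
    X: np.ndarray, labels, n_comp: int = 2, scale: bool = False, positive: str = "UC"
) -> PLSDAModel:
    """Two-class PLS-DA: NIPALS PLS1 regression of y in {0,1} on X.

    Per component: weight ``w ∝ Xᵀy`` (unit norm), score ``t = Xw``,
    loading ``p = Xᵀt / tᵀt``, y-loading ``q = yᵀt / tᵀt``, then deflation
    ``X ← X − t pᵀ``, ``y ← y − t q``.  X is column-centered (and
    unit-variance scaled when ``scale=True``); y is centered.
    """
    X = np.asarray(X, dtype=float)
    y, classes = encode_labels(labels, positive)
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_comp > max_comp:
        logger.warning("n_comp=%d exceeds rank bound %d; truncating", n_comp, max_comp)
        n_comp = max_comp
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xc = (X - x_mean) / x_scale
    y_mean = y.mean()
    yc = y - y_mean

    W = np.zeros((p, n_comp))
    T = np.zeros((n, n_comp))
    P = np.zeros((p, n_comp))
    Q = np.zeros(n_comp)
    Xd, yd = Xc.copy(), yc.copy()
    used = 0
    for a in range(n_comp):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            if a == 0:
                # y carries no covariance with X: keep one null component
                # so downstream metrics report the absence of signal
                logger.warning("PLS found no X-y covariance; null model")
                used = 1
            else:
                logger.warning("PLS deflation exhausted after %d components", a)
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-14:
            break
        pvec = Xd.T @ t / tt
        q = yd @ t / tt
        W[:, a], T[:, a], P[:, a], Q[a] = w, t, pvec, q
        Xd -= np.outer(t, pvec)
        yd = yd - t * q
        used = a + 1
    W, T, P = W[:, :used], T[:, :used], P[:, :used]
    Q = Q[:used]
    # regression vector B = W (PᵀW)^+ q for prediction on centered X
    # (pseudo-inverse keeps the degenerate no-signal model well defined)
    coef = W @ np.linalg.pinv(P.T @ W) @ Q
    return PLSDAModel(W, T, P, Q, coef, x_mean, x_scale, y_mean, classes, used)


def vip(model: PLSDAModel, n_comp: int | None = None) -> np.ndarray:
    """Variable importance in projection over the first ``n_comp`` components.

    VIP_j = sqrt( p · Σ_a SSY_a (w_aj / ‖w_a‖)² / Σ_a SSY_a ) with
    SSY_a = q_a² tᵀ_a t_a; Σ_j VIP_j² = p by construction.
    """
    A = model.n_comp if n_comp is None else min(n_comp, model.n_comp)
    if A < 1:
        raise ValidationError("VIP needs a model with at least one component")
    W = model.weights[:, :A]
    T = model.scores[:, :A]
    Q = model.y_loadings[:A]
    ssy = Q**2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 > 0, wnorm2, 1.0)
    p = W.shape[0]
    return np.sqrt(p * (W**2 / wnorm2) @ ssy / ssy.sum())


@dataclass
class CVMetrics:
    rmse: float
    r2: float
    q2: float
    n_comp: int
    k_folds: int
    seed: int | None
    extras: dict = field(default_factory=dict)


def cross_validate(
    X: np.ndarray, labels, n_comp: int = 2, k: int = 7, seed: int | None = 0,
    scale: bool = False, positive: str = "UC",
) -> CVMetrics:
    """Full-fit RMSE/R² and k-fold cross-validated Q² for a PLS-DA model.

    R² = 1 − RSS/TSS on the full fit; Q² = 1 − PRESS/TSS with PRESS
    accumulated over stratified held-out folds; RMSE on the full fit with y
    coded {0,1}.
    """
    X = np.asarray(X, dtype=float)
    y, _ = encode_labels(labels, positive)
    if k < 2:
        raise ValidationError("need at least 2 folds")
    counts = np.bincount(y.astype(int))
    if counts.min() < k:
        k = int(counts.min())
        if k < 2:
            raise ValidationError("a class is too small to stratify any fold")
        logger.warning("reducing folds to %d to keep both classes per fold", k)
    model = plsda(X, labels, n_comp, scale=scale, positive=positive)
    resid = y - model.predict(X)
    tss = ((y - y.mean()) ** 2).sum()
    rss = (resid**2).sum()
    press = 0.0
    labels = np.asarray(labels)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train, test in splitter.split(X, y):
        fold_model = plsda(X[train], labels[train], n_comp, scale=scale, positive=positive)
        press += ((y[test] - fold_model.predict(X[test])) ** 2).sum()
    return CVMetrics(
        rmse=float(np.sqrt(rss / len(y))),
        r2=float(1 - rss / tss),
        q2=float(1 - press / tss),
        n_comp=model.n_comp,
        k_folds=k,
        seed=seed,
    )


def roc_auc(scores, labels, positive: str = "UC") -> tuple[float, pd.DataFrame]:
    """AUROC with curve points.

    AUROC is the Mann-Whitney U statistic normalized by n1·n2 (ties counted
    half), i.e. the probability that a random positive outranks a random
    negative.  Curve points are (FPR, TPR) at every threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y, _ = encode_labels(labels, positive)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    fpr, tpr, thresholds = roc_curve(y, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc), curve


def fuse_markers(
    vip_values: pd.Series,
    feature_stats: pd.DataFrame,
    vip_threshold: float = 1.0,
    alpha: float = 0.05,
    case: str = "UC",
    control: str = "CTRL",
) -> pd.DataFrame:
    """Fuse multivariate VIP and univariate evidence into marker verdicts.

    A feature is a ``case`` marker iff VIP > ``vip_threshold`` AND
    q < ``alpha`` AND log2FC > 0 (``control`` marker with log2FC < 0);
    otherwise ``none``.
    """
    stats = feature_stats.set_index("feature_id")
    if set(vip_values.index) != set(stats.index):
        raise ValidationError("VIP and univariate results cover different features")
    stats = stats.loc[vip_values.index]
    verdict = np.full(len(stats), "none", dtype=object)
    eligible = (vip_values.to_numpy() > vip_threshold) & (stats["q"].to_numpy() < alpha)
    verdict[eligible & (stats["log2fc"].to_numpy() > 0)] = f"{case}-marker"
    verdict[eligible & (stats["log2fc"].to_numpy() < 0)] = f"{control}-marker"
    return pd.DataFrame(
        {
            "feature_id": vip_values.index,
            "vip": vip_values.to_numpy(),
            "q": stats["q"].to_numpy(),
            "log2fc": stats["log2fc"].to_numpy(),
            "verdict": verdict,
        }
    )
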