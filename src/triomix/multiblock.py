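"""Multiblock integration: ComDim (CCSWA), consensus PCA, multiblock PLS-DA.

All three operate on omic blocks sharing one sample order, each block
Frobenius-normalized beforehand so no omic dominates by raw scale, and
column-centered here (centering after normalization, since the order
changes the norm).  Blocks enter as samples-by-features matrices.

* ComDim extracts common score directions; the non-negative *salience*
  of block b on dimension k measures how much of that block's covariance
  structure the dimension carries.
* MBPCA (consensus PCA) alternates block scores against a super score;
  the unit-norm block-weight vector apportions each super component
  among blocks.
* MBPLS-DA fits the class-coded PLS on the column-wise concatenation of
  the blocks (the joined "unique matrix") and decomposes the super
  weights back into per-block scores and importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import latent
from .core_io import ValidationError

logger = logging.getLogger("triomix")


def _as_centered_blocks(blocks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(blocks) < 1:
        raise ValidationError("need at least one block")
    n_rows = {name: np.asarray(X).shape[0] for name, X in blocks.items()}
    if len(set(n_rows.values())) != 1:
        raise ValidationError(f"blocks disagree on sample count: {n_rows}")
    out = {}
    for name, X in blocks.items():
        X = np.asarray(X, dtype=float)
        if not X.any():
            raise ValidationError(f"block {name!r} is all zero")
        out[name] = X - X.mean(axis=0)
    return out


def _sign_fix(q: np.ndarray) -> np.ndarray:
    j = np.argmax(np.abs(q))
    return -q if q[j] < 0 else q


@dataclass
class ComDimModel:
    block_names: list[str]
    scores: np.ndarray       # samples x K, unit-norm orthogonal columns
    saliences: np.ndarray    # blocks x K, non-negative
    residual_fraction: np.ndarray  # per dimension, of total association SS
    iterations: list[int] = field(default_factory=list)


def comdim(
    blocks: dict[str, np.ndarray], K: int = 2, tol: float = 1e-10, max_iter: int = 1000
) -> ComDimModel:
    """Common components and specific weights analysis.

    Per dimension: with association matrices ``W_b = X_b X_bᵀ`` and
    saliences initialized to 1, alternate (i) ``q`` = dominant unit
    eigenvector of ``Σ_b λ_b W_b`` and (ii) ``λ_b = qᵀ W_b q`` until the
    salience change falls below ``tol``; then deflate every ``W_b`` by
    ``(I − qqᵀ) W_b (I − qqᵀ)``.  At convergence ``Σ_b λ_b`` equals the
    dominant eigenvalue of the weighted sum (fixed-point identity).
    """
    centered = _as_centered_blocks(blocks)
    if len(centered) < 2:
        logger.info("comdim on a single block reduces to PCA of that block")
    names = list(centered)
    n = next(iter(centered.values())).shape[0]
    if K > n - 1:
        raise ValidationError(f"K={K} exceeds sample-rank bound {n - 1}")
    W = {name: X @ X.T for name, X in centered.items()}
    total_ss = sum(np.linalg.norm(Wb) ** 2 for Wb in W.values())

    scores = np.zeros((n, K))
    saliences = np.zeros((len(names), K))
    residual = np.zeros(K)
    iterations = []
    for k in range(K):
        lam = np.ones(len(names))
        q = None
        for it in range(1, max_iter + 1):
            M = sum(l * W[name] for l, name in zip(lam, names))
            eigvals, eigvecs = np.linalg.eigh(M)
            q = _sign_fix(eigvecs[:, -1])
            new_lam = np.array([q @ W[name] @ q for name in names])
            delta = np.max(np.abs(new_lam - lam))
            lam = new_lam
            if delta < tol:
                break
        else:
            logger.warning("comdim dimension %d: no convergence, last dlambda=%.3e", k, delta)
        iterations.append(it)
        scores[:, k] = q
        saliences[:, k] = lam
        proj = np.eye(n) - np.outer(q, q)
        for name in names:
            W[name] = proj @ W[name] @ proj
        residual[k] = sum(np.linalg.norm(W[name]) ** 2 for name in names) / total_ss
    order = np.argsort(-saliences.sum(axis=0), kind="stable")
    return ComDimModel(
        names, scores[:, order], saliences[:, order], residual[order],
        [iterations[i] for i in order],
    )


@dataclass
class MBPCAModel:
    block_names: list[str]
    super_scores: np.ndarray            # samples x A
    block_scores: dict[str, np.ndarray]  # each samples x A
    block_loadings: dict[str, np.ndarray]
    block_weights: np.ndarray           # blocks x A, unit norm per column
    explained_block_variance: np.ndarray  # blocks x A, fraction of block SS
    iterations: list[int] = field(default_factory=list)


def mbpca(
    blocks: dict[str, np.ndarray], n_comp: int = 2, tol: float = 1e-10,
    max_iter: int = 1000,
) -> MBPCAModel:
    """Consensus PCA by the NIPALS super-score algorithm.

    Per component, starting from the highest-variance column: block
    loadings ``p_b = X_bᵀ t / tᵀt``, block scores ``t_b = X_b p_b / ‖p_b‖``,
    block-weight vector ``w = Tᵀ t / tᵀt`` normalized, super score
    ``t = T w``; iterate to convergence, then deflate each block against
    the converged super score.
    """
    centered = _as_centered_blocks(blocks)
    names = list(centered)
    n = next(iter(centered.values())).shape[0]
    if n_comp > n - 1:
        raise ValidationError(f"n_comp={n_comp} exceeds sample-rank bound {n - 1}")
    Xd = {name: X.copy() for name, X in centered.items()}
    block_ss = {name: np.linalg.norm(X) ** 2 for name, X in centered.items()}

    super_scores = np.zeros((n, n_comp))
    block_scores = {name: np.zeros((n, n_comp)) for name in names}
    block_loadings = {name: np.zeros((X.shape[1], n_comp)) for name, X in centered.items()}
    block_weights = np.zeros((len(names), n_comp))
    evb = np.zeros((len(names), n_comp))
    iterations = []
    for a in range(n_comp):
        concat = np.column_stack([Xd[name] for name in names])
        t = concat[:, np.argmax(concat.var(axis=0))].copy()
        if not t.any():
            raise ValidationError("blocks fully deflated before requested components")
        for it in range(1, max_iter + 1):
            T = np.zeros((n, len(names)))
            for b, name in enumerate(names):
                p = Xd[name].T @ t / (t @ t)
                pn = np.linalg.norm(p)
                T[:, b] = Xd[name] @ p / pn if pn > 0 else 0.0
            w = T.T @ t / (t @ t)
            w /= np.linalg.norm(w)
            t_new = T @ w
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t)):
                t = t_new
                break
            t = t_new
        else:
            logger.warning("mbpca component %d did not converge in %d iterations", a, max_iter)
        iterations.append(it)
        t = _sign_fix(t)
        super_scores[:, a] = t
        for b, name in enumerate(names):
            p = Xd[name].T @ t / (t @ t)
            pn = np.linalg.norm(p)
            block_loadings[name][:, a] = p
            block_scores[name][:, a] = Xd[name] @ p / pn if pn > 0 else 0.0
            deflated = np.outer(t, p)
            evb[b, a] = np.linalg.norm(deflated) ** 2 / block_ss[name]
            Xd[name] -= deflated
        block_weights[:, a] = _recompute_block_weights(t, block_scores, names, a)
    return MBPCAModel(
        names, super_scores, block_scores, block_loadings, block_weights, evb, iterations
    )


def _recompute_block_weights(t, block_scores, names, a) -> np.ndarray:
    T = np.column_stack([block_scores[name][:, a] for name in names])
    w = T.T @ t / (t @ t)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


@dataclass
class MBPLSDAModel:
    block_names: list[str]
    model: latent.PLSDAModel             # fit on the concatenated superblock
    block_slices: dict[str, slice]
    block_scores: dict[str, np.ndarray]  # t_b = X_b w_b per component
    block_importance: np.ndarray         # blocks x A, sums to 1 per component
    vip: np.ndarray                      # per concatenated feature

    def predict(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        X = np.column_stack([np.asarray(blocks[name], float) for name in self.block_names])
        return self.model.predict(X)


def mbplsda(
    blocks: dict[str, np.ndarray], labels, n_comp: int = 2,
    k_folds: int = 7, seed: int | None = 0, positive: str = "UC",
) -> tuple[MBPLSDAModel, latent.CVMetrics, float]:
    """Supervised multiblock PLS-DA on the concatenated superblock.

    Fits :func:`triomix.latent.plsda` on the column-wise concatenation,
    recovers per-block scores ``t_b = X_b w_b`` from each block's slice of
    the super weights, reports block importance ``‖w_b‖²`` per component
    (the super weights are unit norm, so importances sum to 1), multiblock
    VIPs, cross-validation metrics and the training-fit AUROC.
    """
    names = list(blocks)
    mats = {name: np.asarray(blocks[name], dtype=float) for name in names}
    _as_centered_blocks(mats)  # shape/zero validation only
    X = np.column_stack([mats[name] for name in names])
    slices = {}
    start = 0
    for name in names:
        stop = start + mats[name].shape[1]
        slices[name] = slice(start, stop)
        start = stop
    model = latent.plsda(X, labels, n_comp, positive=positive)
    A = model.n_comp
    importance = np.zeros((len(names), A))
    block_scores = {}
    Xc = (X - model.x_mean) / model.x_scale
    for b, name in enumerate(names):
        w_b = model.weights[slices[name], :A]
        importance[b] = (w_b**2).sum(axis=0)
        block_scores[name] = Xc[:, slices[name]] @ w_b
    vip_values = latent.vip(model)
    cv = latent.cross_validate(X, labels, n_comp, k=k_folds, seed=seed, positive=positive)
    auroc, _ = latent.roc_auc(model.predict(X), labels, positive=positive)
    mb_model = MBPLSDAModel(names, model, slices, block_scores, importance, vip_values)
    return mb_model, cv, auroc
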