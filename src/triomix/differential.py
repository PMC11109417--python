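"""Univariate screening and LDA effect size.

Per-feature Mann-Whitney U tests with Benjamini-Hochberg FDR and log2 fold
changes; a two-class LDA effect-size scorer in the LEfSe style
(Kruskal-Wallis screen, per-class bootstrap, regularized linear
discriminant, log10 effect sizes with a magnitude threshold); and the
confounder screen that asks whether cohort covariates, rather than disease
status, explain the omic signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import diversity
from .core_io import AlignedStudy, FeatureTable, ValidationError
from .preprocess import relative_abundance

logger = logging.getLogger("triomix")

CASE_GROUP = "UC"
CONTROL_GROUP = "CTRL"


def mann_whitney_screen(
    table: FeatureTable, labels, alpha: float = 0.05,
    case: str = CASE_GROUP, control: str = CONTROL_GROUP,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U with BH-FDR and log2FC.

    The exact null distribution is used for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's ``method="auto"``
    switch).  log2FC compares group means of ``case`` over ``control`` with
    an offset of half the table's smallest positive value, so features
    absent from one group get a finite fold change.  BH adjustment is across
    the features of this one table.
    """
    labels = np.asarray(labels)
    x_mask, y_mask = labels == case, labels == control
    if x_mask.sum() < 3 or y_mask.sum() < 3:
        raise ValidationError("each group needs at least 3 samples")
    values = table.values
    positive = values[values > 0]
    eps = 0.5 * positive.min() if positive.size else 0.5
    records = []
    for i, fid in enumerate(table.feature_ids):
        x, y = values[i, x_mask], values[i, y_mask]
        if np.ptp(values[i]) == 0:  # constant feature: no evidence either way
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            u, p = mannwhitneyu(x, y, alternative="two-sided", method="auto")
        log2fc = np.log2((x.mean() + eps) / (y.mean() + eps))
        records.append((fid, float(u), float(p), log2fc))
    df = pd.DataFrame(records, columns=["feature_id", "U", "p", "log2fc"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["direction"] = np.where(df["log2fc"] > 0, case, np.where(df["log2fc"] < 0, control, "none"))
    df["significant"] = df["q"] < alpha
    return df[["feature_id", "U", "p", "q", "log2fc", "direction", "significant"]]


@dataclass
class LefseParams:
    """LDA effect-size knobs (reference-style defaults)."""

    kw_alpha: float = 0.05
    n_boot: int = 30
    subsample_frac: float = 2.0 / 3.0
    lda_threshold: float = 2.0
    feature_scale: float = 1e6
    ridge: float = 1e-6  # within-class scatter regularization
    seed: int = 0


def _lda_direction(X: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Unit direction of the two-class regularized linear discriminant."""
    m1, m0 = X[y].mean(axis=0), X[~y].mean(axis=0)
    centered = np.vstack([X[y] - m1, X[~y] - m0])
    sw = centered.T @ centered / max(len(X) - 2, 1)
    sw[np.diag_indices_from(sw)] += ridge * (1.0 + np.trace(sw) / sw.shape[0])
    w = np.linalg.solve(sw, m1 - m0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse(
    table: FeatureTable, labels, params: LefseParams | None = None,
    case: str = CASE_GROUP, control: str = CONTROL_GROUP,
) -> pd.DataFrame:
    """LDA effect sizes for two-group relative-abundance data.

    Stages: (1) per-feature Kruskal-Wallis screen at ``kw_alpha`` after BH
    adjustment; (2) surviving features rescaled to sum ``feature_scale`` per
    sample; (3) ``n_boot`` bootstrap rounds subsampling ``subsample_frac``
    of each class and fitting a one-discriminant regularized LDA, with the
    per-feature effect = |class-mean difference + discriminant-projected
    difference| / 2; (4) score = sign x log10(1 + mean effect), where
    features enriched in ``case`` carry *negative* scores (figure
    convention) and the enriched group is stored explicitly.  Features with
    |score| >= ``lda_threshold`` are flagged.
    """
    params = params or LefseParams()
    labels = np.asarray(labels)
    y = labels == case
    if not y.any() or y.all():
        raise ValidationError("both groups must be present")

    values = table.values
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("all-zero sample in lefse input")
    values = values / totals  # enforce the relative-abundance contract
    kw_p = np.ones(len(table.feature_ids))
    for i in range(values.shape[0]):
        x1, x0 = values[i, y], values[i, ~y]
        if np.ptp(values[i]) == 0:
            continue
        kw_p[i] = kruskal(x1, x0).pvalue
    kw_q = multipletests(kw_p, method="fdr_bh")[1]
    surviving = np.nonzero(kw_q < params.kw_alpha)[0]
    if surviving.size < 2:
        logger.info("lefse: %d features survive the Kruskal-Wallis screen; "
                    "need >= 2, returning empty result", surviving.size)
        return pd.DataFrame(columns=["feature_id", "lda_score", "enriched_group", "significant"])

    sub = values[surviving]
    col_sums = sub.sum(axis=0)
    if (col_sums == 0).any():
        raise ValidationError("sample with zero total after the screen")
    X = (sub / col_sums * params.feature_scale).T  # samples x features

    rng = np.random.default_rng(params.seed)
    idx1, idx0 = np.nonzero(y)[0], np.nonzero(~y)[0]
    # draw subsamples in an order fixed by the partition, not the label
    # names, so relabeling the classes flips scores exactly
    parts = sorted((idx1, idx0), key=lambda idx: idx.min())
    sizes = [max(2, int(round(params.subsample_frac * idx.size))) for idx in parts]
    effects = np.zeros((params.n_boot, surviving.size))
    for b in range(params.n_boot):
        take = np.concatenate(
            [rng.choice(idx, size=k, replace=False) for idx, k in zip(parts, sizes)]
        )
        Xb, yb = X[take], y[take]
        m1, m0 = Xb[yb].mean(axis=0), Xb[~yb].mean(axis=0)
        w = _lda_direction(Xb, yb, params.ridge)
        proj_diff = w * float(w @ (m1 - m0))
        effects[b] = np.abs((m1 - m0) + proj_diff) / 2.0
    mean_effect = effects.mean(axis=0)

    m1_full, m0_full = X[y].mean(axis=0), X[~y].mean(axis=0)
    enriched = np.where(m1_full >= m0_full, case, control)
    magnitude = np.log10(1.0 + mean_effect)
    score = np.where(enriched == case, -magnitude, magnitude)
    df = pd.DataFrame(
        {
            "feature_id": [table.feature_ids[i] for i in surviving],
            "lda_score": score,
            "enriched_group": enriched,
        }
    )
    df["significant"] = np.abs(df["lda_score"]) >= params.lda_threshold
    return df


def median_split(values: pd.Series) -> pd.Series:
    """Dichotomize a continuous covariate at its median (<= median vs >)."""
    med = values.median()
    return pd.Series(
        np.where(values <= med, f"le_{med:g}", f"gt_{med:g}"),
        index=values.index,
    )


def confounder_screen(
    study: AlignedStudy,
    variables: list[str],
    median_split_vars: list[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Screen metadata covariates for confounding across all omic blocks.

    Categorical variables are tested with the LDA effect-size screen per
    omic; continuous variables (``median_split_vars``) are dichotomized at
    the median and additionally tested with PERMANOVA on Bray-Curtis
    distances.  A variable is flagged as a potential confounder when any
    omic yields significant features at FDR ``alpha`` or a PERMANOVA
    p < ``alpha``.
    """
    median_split_vars = median_split_vars or []
    meta = study.metadata.loc[study.sample_ids]
    rows = []
    for var in variables:
        if var not in meta.columns:
            raise ValidationError(f"metadata column {var!r} not found")
        col = meta[var]
        continuous = var in median_split_vars
        labels = median_split(pd.to_numeric(col, errors="coerce")) if continuous else col
        labels = labels.astype("object")
        mask = labels.notna().to_numpy()
        lab = labels[mask].astype(str).to_numpy()
        levels, counts = np.unique(lab, return_counts=True)
        if len(levels) < 2 or (counts < 3).any():
            logger.warning("confounder screen skipped %r (degenerate levels)", var)
            continue
        case, control = levels[0], levels[1]
        for name, block in study.blocks.items():
            sub = block.subset_samples([s for s, m in zip(study.sample_ids, mask) if m])
            rel = relative_abundance(sub)
            scores = lefse(
                rel, lab, LefseParams(kw_alpha=alpha, seed=0), case=case, control=control
            )
            n_sig = int(scores["significant"].sum()) if len(scores) else 0
            perma_p = np.nan
            if continuous or counts.min() >= 2:
                dm = diversity.bray_curtis(rel)
                perma_p = diversity.permanova(dm, lab, n_perm=n_perm, seed=seed).p_value
            rows.append((var, name, n_sig, perma_p))
    report = pd.DataFrame(rows, columns=["variable", "omic", "n_significant", "permanova_p"])
    if report.empty:
        report["potential_confounder"] = pd.Series(dtype=bool)
        return report
    verdict = (
        report.groupby("variable")
        .apply(
            lambda g: bool(
                (g["n_significant"] > 0).any() or (g["permanova_p"] < alpha).any()
            ),
            include_groups=False,
        )
        .rename("potential_confounder")
    )
    return report.merge(verdict, on="variable")
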