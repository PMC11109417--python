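"""Alpha/beta diversity and permutation testing.

Shannon diversity per sample, Bray-Curtis dissimilarity matrices, a
seeded PERMANOVA (pseudo-F under label permutation, Anderson's
sums-of-squares formulation), and the intragroup-distance comparison that
asks whether one group's samples are more dispersed than the other's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .core_io import FeatureTable, ValidationError

logger = logging.getLogger("triomix")


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # square symmetric, zero diagonal
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    extras: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValidationError("p-value outside (0, 1]")


def shannon(table: FeatureTable, base: float = 2.0) -> pd.Series:
    """Shannon-Wiener index H per sample: -sum p log_base p over positive p."""
    values = table.values
    col_sums = values.sum(axis=0)
    if (col_sums == 0).any():
        bad = [s for s, z in zip(table.sample_ids, col_sums == 0) if z]
        raise ValidationError(f"all-zero samples: {bad}")
    p = values / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=0) / np.log(base)
    return pd.Series(h, index=table.sample_ids, name="shannon")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    X = table.values.T  # samples x features
    if (X.sum(axis=1) == 0).any():
        raise ValidationError("all-zero sample: Bray-Curtis undefined")
    dm = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, dm, "braycurtis")


def _within_group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F = (SS_among / (a-1)) / (SS_within / (n-a)) with sums of squares
    computed from squared distances; the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under random relabeling.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != len(dm.sample_ids):
        raise ValidationError("labels length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    a = len(groups)
    d2 = dm.values**2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_within = _within_group_ss(d2, lab)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(f_obs, p, n_perm, seed)


def intragroup_distance_test(dm: DistanceMatrix, labels) -> PermutationTestResult:
    """Compare within-group pairwise distances between two groups.

    All within-group pairs are pooled per group and compared with a
    two-sided Mann-Whitney U test.  Pairs sharing a sample are not
    independent, so the p-value is indicative rather than exact; the result
    carries per-group median distances in ``extras``.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValidationError("intragroup distance test needs exactly two groups")
    dist_by_group = {}
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        if idx.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
        iu = np.triu_indices(idx.size, k=1)
        dist_by_group[g] = dm.values[np.ix_(idx, idx)][iu]
    x, y = dist_by_group[groups[0]], dist_by_group[groups[1]]
    medians = {str(g): float(np.median(v)) for g, v in dist_by_group.items()}
    if np.ptp(np.concatenate([x, y])) == 0:
        logger.warning("intragroup distances all tied; test degenerate, p = 1")
        u, p = len(x) * len(y) / 2.0, 1.0
    else:
        u, p = mannwhitneyu(x, y, alternative="two-sided")
    logger.info(
        "intragroup distances treated as exchangeable observations; "
        "pairs sharing a sample are dependent"
    )
    return PermutationTestResult(float(u), float(p), 0, None, extras={"medians": medians})
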