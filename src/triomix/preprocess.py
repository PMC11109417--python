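"""Feature filtering and the three normalizations.

Per-omic prevalence/abundance filters (taxa kept when present in at least
25% of samples or, for bacteria, when their mean relative abundance clears
0.01; metabolites kept at 10% prevalence), rarefaction of count tables,
per-sample relative abundance, cumulative sum scaling (CSS), and whole-block
Frobenius normalization used to put taxa and metabolite blocks on one scale
before multiblock integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import FeatureTable, ValidationError

logger = logging.getLogger("triomix")


@dataclass
class FilterRule:
    """Retention rule: keep features with prevalence >= ``min_prevalence``
    or (when set) mean relative abundance >= ``min_rel_abundance``."""

    min_prevalence: float = 0.25
    min_rel_abundance: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must lie in [0, 1]")
        if self.min_rel_abundance is not None and not 0 <= self.min_rel_abundance <= 1:
            raise ValueError("min_rel_abundance must lie in [0, 1]")


#: Per-omic defaults: bacteria are removed only when BOTH rare (<25% of
#: samples) and low-abundance (<1% mean relative abundance); fungi and
#: metabolites are removed on prevalence alone (<25% and <10%).
DEFAULT_FILTERS = {
    "bacteria": FilterRule(0.25, 0.01),
    "fungi": FilterRule(0.25, None),
    "metabolite": FilterRule(0.10, None),
}


def prevalence_abundance_filter(table: FeatureTable, rule: FilterRule) -> FeatureTable:
    """Drop rare features; see :class:`FilterRule` for the retention logic."""
    if table.value_kind not in ("count", "concentration"):
        raise ValidationError(
            f"filter expects raw counts or concentrations, got {table.value_kind!r}"
        )
    values = table.values
    prevalence = (values > 0).mean(axis=1)
    keep = prevalence >= rule.min_prevalence
    if rule.min_rel_abundance is not None:
        col_sums = values.sum(axis=0)
        if (col_sums == 0).any():
            raise ValidationError("all-zero sample encountered during filtering")
        mean_rel = (values / col_sums).mean(axis=1)
        keep |= mean_rel >= rule.min_rel_abundance
    if not keep.any():
        raise ValidationError(
            "filter removed every feature; relax min_prevalence/min_rel_abundance"
        )
    removed = [fid for fid, k in zip(table.feature_ids, keep) if not k]
    if removed:
        logger.info("%s filter removed %d features", table.omic, len(removed))
    return table.subset_features([fid for fid, k in zip(table.feature_ids, keep) if k])


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total counts are dropped with a
    warning.  Deterministic given ``seed``.
    """
    if table.value_kind != "count":
        raise ValidationError("rarefy requires a count table")
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = np.round(table.values).astype(np.int64)
    totals = counts.sum(axis=0)
    kept_cols = []
    out_cols = []
    for j, sid in enumerate(table.sample_ids):
        if totals[j] < depth:
            logger.warning("rarefy dropped sample %s (total %d < %d)", sid, totals[j], depth)
            continue
        kept_cols.append(sid)
        if totals[j] == depth:
            out_cols.append(counts[:, j])
        else:
            out_cols.append(rng.multivariate_hypergeometric(counts[:, j], depth))
    if not kept_cols:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    sub = table.subset_samples(kept_cols)
    return sub.with_values(np.column_stack(out_cols), value_kind="count")


def min_sample_depth(table: FeatureTable) -> int:
    """Default rarefaction depth: the smallest per-sample total."""
    return int(table.values.sum(axis=0).min())


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Scale each sample to sum 1."""
    values = table.values
    col_sums = values.sum(axis=0)
    zero = col_sums == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValidationError(f"all-zero samples: {bad}")
    return table.with_values(values / col_sums, value_kind="relative")


def css_normalize(
    table: FeatureTable, quantile: float | None = 0.5, scale: float = 1000.0
) -> FeatureTable:
    """Cumulative sum scaling.

    For sample j let q_j be the ``quantile``-quantile (linear interpolation)
    of its positive counts and s_j the sum of counts at or below q_j; output
    is ``c_ij * scale / s_j``.  ``quantile=None`` selects the quantile
    adaptively per table (see :func:`css_adaptive_quantile`); the default
    0.5 is stable on small tables.  ``quantile=1`` includes every count in
    s_j, i.e. total-sum scaling.
    """
    if table.value_kind != "count":
        raise ValidationError("css_normalize requires a count table")
    if quantile is None:
        quantile = css_adaptive_quantile(table)
        logger.info("CSS adaptive quantile = %.2f", quantile)
    if not 0 < quantile <= 1:
        raise ValueError("CSS quantile must lie in (0, 1]")
    if scale <= 0:
        raise ValueError("CSS scale must be positive")
    values = table.values
    out = np.empty_like(values)
    for j, sid in enumerate(table.sample_ids):
        col = values[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise ValidationError(f"sample {sid} has no positive counts")
        q = np.quantile(positive, quantile)  # linear (type-7) interpolation
        s = col[col <= q].sum()
        if s == 0:
            raise ValidationError(f"sample {sid}: no counts at or below quantile {quantile}")
        out[:, j] = col * scale / s
    return table.with_values(out, value_kind="css")


def css_adaptive_quantile(table: FeatureTable, grid_step: float = 0.05,
                          instability: float = 0.1) -> float:
    """Data-driven CSS quantile choice.

    Scans candidate quantiles and returns the smallest at which the median
    relative spread of per-sample quantile values across samples exceeds
    ``instability`` — the point where sample count distributions start to
    diverge.  Falls back to 0.5 when the spread never exceeds the cutoff.
    """
    values = table.values
    qs = np.arange(grid_step, 1.0, grid_step)
    per_sample = np.array(
        [np.quantile(values[:, j][values[:, j] > 0], qs) for j in range(values.shape[1])]
    )  # samples x quantiles
    ref = np.median(per_sample, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        spread = np.nanmedian(
            np.abs(per_sample - ref) / np.where(ref > 0, ref, np.nan), axis=0
        )
    above = np.nonzero(spread > instability)[0]
    return float(qs[above[0]]) if above.size else 0.5


def log_transform(table: FeatureTable, base: float = 2.0, offset: float = 1.0) -> FeatureTable:
    """Elementwise log(offset + x); the usual companion of CSS scaling.

    Count-derived abundances are heavy-tailed across features, so latent
    models fit on the raw scale see only the most abundant taxa; the log
    puts fold changes on a common additive scale.  value_kind is preserved.
    """
    if offset <= 0:
        raise ValueError("offset must be positive to keep zeros finite")
    return table.with_values(np.log(offset + table.values) / np.log(base))


def frobenius_normalize(table: FeatureTable) -> FeatureTable:
    """Divide the whole block by its Frobenius norm (output norm = 1).

    Used before multiblock integration so that blocks measured in different
    units (relative abundances vs mg/kg) carry equal total scale.
    """
    values = table.values
    norm = np.linalg.norm(values)
    if norm == 0:
        raise ValidationError("cannot Frobenius-normalize an all-zero block")
    return table.with_values(values / norm, value_kind="frobenius")
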