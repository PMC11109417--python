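"""Reading, validation and alignment of multi-omic feature tables.

The package works on three kinds of blocks measured on one stool-sample
cohort: bacterial and fungal amplicon count tables (features x samples,
non-negative integers) and a metabolite concentration table (compounds x
samples, mg/kg).  This module defines the in-memory containers
(:class:`FeatureTable`, :class:`AlignedStudy`), the TSV/CSV readers and
writers, and the sample-alignment step that puts every block on one shared,
metadata-ordered sample list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("triomix")

OMICS = ("bacteria", "fungi", "metabolite")
VALUE_KINDS = ("count", "relative", "css", "concentration", "frobenius")
GROUPS = ("UC", "CTRL")


class ValidationError(ValueError):
    """An input table or metadata record violates a structural invariant."""


@dataclass
class FeatureTable:
    """A features-by-samples matrix for one omic block.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
        All values must be non-negative; integer-valued when
        ``value_kind == "count"``.
    omic
        One of ``bacteria``, ``fungi``, ``metabolite``.
    value_kind
        One of ``count``, ``relative``, ``css``, ``concentration``,
        ``frobenius``.
    """

    data: pd.DataFrame
    omic: str
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.omic not in OMICS:
            raise ValidationError(f"unknown omic {self.omic!r}; expected one of {OMICS}")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite values in feature table")
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative values in features: {bad}")
        if self.value_kind == "count" and not np.allclose(values, np.round(values)):
            raise ValidationError("value_kind='count' requires integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Matrix of shape (n_features, n_samples) as float."""
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_values(self, values: np.ndarray, value_kind: str | None = None) -> "FeatureTable":
        """Same ids/omic, new matrix (and optionally new value kind)."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return FeatureTable(df, self.omic, value_kind or self.value_kind)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(sample_ids)], self.omic, self.value_kind)

    def subset_features(self, feature_ids: list[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(feature_ids), :], self.omic, self.value_kind)


def read_feature_table(
    path, omic: str, value_kind: str = "count", samples_as_rows: bool = False
) -> FeatureTable:
    """Read a delimited feature table (first column = feature ids).

    Tables are features-as-rows by default, the dominant amplicon-table
    dialect; pass ``samples_as_rows=True`` to transpose on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"empty feature table: {path}")
    if samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:  # non-numeric cell
        raise ValidationError(f"non-numeric value in {path}: {exc}") from exc
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        # sparse GC-MS tables leave undetected compounds blank; store as 0
        logger.info("%s: %d missing entries stored as 0", path, n_missing)
        df = df.fillna(0.0)
    return FeatureTable(df, omic=omic, value_kind=value_kind)


def write_feature_table(table: FeatureTable, path) -> None:
    data = table.data
    if table.value_kind == "count":
        data = data.astype(np.int64)
    data.to_csv(path, sep="\t", index_label="feature_id")


REQUIRED_METADATA = ("sample_id", "group")
_GROUP_ALIASES = {"UC": "UC", "CTRL": "CTRL", "CONTROL": "CTRL", "HC": "CTRL"}
_GENDER_ALIASES = {"M": "M", "MALE": "M", "F": "F", "FEMALE": "F"}


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata CSV into a DataFrame indexed by sample id.

    Required columns: ``sample_id`` and ``group`` (UC/CTRL).  Optional
    columns (gender, age, therapy flags) keep missing values as NA; any
    unrecognised gender label becomes NA rather than an error.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in REQUIRED_METADATA:
        if col not in df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    group = df["group"].astype(str).str.strip().str.upper().map(_GROUP_ALIASES)
    if group.isna().any() or df["group"].isna().any():
        bad = sorted(df.loc[group.isna(), "group"].astype(str).unique())
        raise ValidationError(
            f"unrecognized group labels {bad}; allowed labels are {list(GROUPS)}"
        )
    df = df.copy()
    df["group"] = group
    if "gender" in df.columns:
        df["gender"] = (
            df["gender"].astype("string").str.strip().str.upper().map(_GENDER_ALIASES)
        )
    if "age" in df.columns:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        if (df["age"].dropna() < 0).any():
            raise ValidationError("negative age in metadata")
    return df.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


@dataclass
class AlignedStudy:
    """Omic blocks sharing one ordered sample list plus their metadata."""

    blocks: dict[str, FeatureTable]
    metadata: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("AlignedStudy requires at least one block")
        if not self.sample_ids:
            self.sample_ids = list(next(iter(self.blocks.values())).sample_ids)
        for name, block in self.blocks.items():
            if block.sample_ids != self.sample_ids:
                raise ValidationError(f"block {name!r} samples differ from shared order")
        missing = [s for s in self.sample_ids if s not in self.metadata.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")

    @property
    def groups(self) -> np.ndarray:
        """Group label per sample, in shared sample order."""
        return self.metadata.loc[self.sample_ids, "group"].to_numpy()

    def drop_block(self, name: str) -> "AlignedStudy":
        blocks = {k: v for k, v in self.blocks.items() if k != name}
        return AlignedStudy(blocks, self.metadata, list(self.sample_ids))


def align_samples(blocks: dict[str, FeatureTable], metadata: pd.DataFrame) -> AlignedStudy:
    """Restrict all blocks to the common sample set, in metadata order.

    Metadata order is the single authoritative ordering; ids present in some
    blocks but not all (or lacking metadata) are dropped with a log message.
    """
    if not blocks:
        raise ValidationError("align_samples requires at least one block")
    shared = set(metadata.index)
    for block in blocks.values():
        shared &= set(block.sample_ids)
    ordered = [s for s in metadata["sample_id"] if s in shared]
    if not ordered:
        raise ValidationError("no samples shared by all blocks and metadata")
    all_ids = set(metadata.index)
    for block in blocks.values():
        all_ids |= set(block.sample_ids)
    dropped = sorted(all_ids - shared)
    if dropped:
        logger.info("align_samples dropped %d ids: %s", len(dropped), dropped)
    aligned = {name: block.subset_samples(ordered) for name, block in blocks.items()}
    return AlignedStudy(aligned, metadata.loc[ordered], ordered)
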