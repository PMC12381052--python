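"""Sample-by-feature abundance tables: data model, I/O and transforms.

The working unit throughout the pipeline is a non-negative samples x
features matrix.  Counts are converted to per-sample relative abundances,
optionally log(x+1)-transformed, and features are prevalence-filtered at a
relative-abundance threshold (default 0.1% in at least one sample) before
any dissimilarity-based analysis.

Tables are exchanged as tab-separated UTF-8 text with a ``sample_id`` (or
``feature_id``) header cell, which keeps every intermediate diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALES = ("counts", "relative", "log1p-relative")

#: taxonomy ranks a feature-metadata table may carry as lineage columns
LINEAGE_RANKS = ("class", "genus", "species")


class TableError(ValueError):
    """Raised when a table violates the data-model contract."""


@dataclass
class FeatureTable:
    """A samples x features matrix of non-negative abundances.

    Parameters
    ----------
    data:
        DataFrame with unique sample ids as index and unique feature ids
        as columns; all values finite and >= 0.
    scale:
        One of ``counts``, ``relative`` (non-zero rows sum to 1) or
        ``log1p-relative`` (natural log(x+1) of a relative table).
    feature_meta:
        Optional per-feature records indexed by feature id.  Taxonomic
        tables carry lineage columns (``class``, ``genus``); functional
        tables carry ``rank`` (EC1..EC4, gene) and ``source`` (DNA/RNA).
    zero_samples:
        Sample ids whose row was all-zero at construction.  They are kept
        in the table but must be excluded from dissimilarity computations.
    """

    data: pd.DataFrame
    scale: str = "counts"
    feature_meta: pd.DataFrame | None = None
    zero_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise TableError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise TableError("table contains non-finite values")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise TableError(f"duplicate feature id {dup!r}")
        if self.scale == "relative":
            sums = values.sum(axis=1)
            nonzero = ~np.isin(self.data.index, list(self.zero_samples))
            if values.size and not np.allclose(sums[nonzero], 1.0, atol=1e-9):
                raise TableError("relative-scale rows must sum to 1 +- 1e-9")
        if self.feature_meta is not None:
            missing = self.data.columns.difference(self.feature_meta.index)
            if len(missing):
                raise TableError(f"feature_meta missing records for {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def meta_for(self, columns: list[str]) -> pd.DataFrame | None:
        if self.feature_meta is None:
            return None
        return self.feature_meta.loc[columns]


@dataclass
class SampleMetadata:
    """Per-sample clinical records: patient id and binary diagnosis."""

    data: pd.DataFrame  # index: sample_id; columns include patient_id, diagnosis

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")
        for col in ("patient_id", "diagnosis"):
            if col not in self.data.columns:
                raise TableError(f"metadata lacks required column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def diagnosis(self, sample_ids: list[str] | None = None) -> pd.Series:
        s = self.data["diagnosis"]
        return s if sample_ids is None else s.loc[sample_ids]

    def patients(self, sample_ids: list[str] | None = None) -> pd.Series:
        s = self.data["patient_id"]
        return s if sample_ids is None else s.loc[sample_ids]

    def validate_against(self, table: FeatureTable) -> None:
        """Every sample of *table* must have exactly one metadata record."""
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise TableError(f"samples without metadata: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# I/O


def read_table(path, orientation: str = "samples-in-rows") -> FeatureTable:
    """Read a TSV abundance table into a counts-scale :class:`FeatureTable`.

    The first cell holds the id-column name; ``orientation`` states whether
    rows are samples or features, and the returned table is always
    samples-in-rows.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise TableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TableError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "features-in-rows":
        df = df.T
    return FeatureTable(df, scale="counts")


def write_table(table: FeatureTable, path, orientation: str = "samples-in-rows") -> None:
    """Write a table as TSV (inverse of :func:`read_table`)."""
    df = table.data if orientation == "samples-in-rows" else table.data.T
    df = df.rename_axis("sample_id" if orientation == "samples-in-rows" else "feature_id")
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms


def to_relative(table: FeatureTable) -> FeatureTable:
    """Close each sample row to proportions; all-zero rows kept and flagged."""
    if table.scale != "counts":
        raise TableError(f"to_relative expects counts, got {table.scale}")
    values = table.values
    sums = values.sum(axis=1)
    zero = sums == 0
    out = np.divide(values, np.where(zero, 1.0, sums)[:, None])
    data = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    flagged = tuple(np.asarray(table.sample_ids)[zero])
    return FeatureTable(data, scale="relative", feature_meta=table.feature_meta,
                        zero_samples=flagged)


def log1p_transform(table: FeatureTable) -> FeatureTable:
    """Element-wise natural log(x + 1); only defined on relative tables."""
    if table.scale != "relative":
        raise TableError(f"log1p_transform expects relative, got {table.scale}")
    data = pd.DataFrame(np.log1p(table.values), index=table.data.index,
                        columns=table.data.columns)
    return FeatureTable(data, scale="log1p-relative",
                        feature_meta=table.feature_meta,
                        zero_samples=table.zero_samples)


def _relative_view(table: FeatureTable) -> np.ndarray:
    if table.scale == "counts":
        return to_relative(table).values
    if table.scale == "relative":
        return table.values
    raise TableError("prevalence_filter needs a counts or relative table")


def prevalence_filter(table: FeatureTable, min_rel: float = 0.001,
                      min_samples: int = 1) -> tuple[FeatureTable, dict]:
    """Keep features reaching ``min_rel`` relative abundance in >= ``min_samples`` samples.

    The default (0.1% in at least one sample) is the screening rule applied
    to both the species and the EC tables before downstream analysis.
    Returns the filtered table and a ``{"kept": k, "dropped": d}`` report.
    """
    if not 0 < min_rel <= 1:
        raise TableError(f"min_rel must be in (0, 1], got {min_rel}")
    rel = _relative_view(table)
    keep = (rel >= min_rel).sum(axis=0) >= min_samples
    kept_cols = table.data.columns[keep]
    meta = table.meta_for(list(kept_cols))
    out = FeatureTable(table.data.loc[:, kept_cols], scale=table.scale,
                       feature_meta=meta, zero_samples=table.zero_samples)
    report = {"kept": int(keep.sum()), "dropped": int((~keep).sum())}
    return out, report


def aggregate_rank(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum feature columns sharing a taxonomy label at *rank* (genus/class).

    Per-sample totals are conserved exactly; the output's feature ids are
    the rank labels.
    """
    if table.feature_meta is None or rank not in table.feature_meta.columns:
        raise TableError(f"feature_meta lacks a {rank!r} lineage column")
    labels = table.feature_meta.loc[table.data.columns, rank].astype(str)
    grouped = table.data.T.groupby(labels.values, sort=True).sum().T
    meta = pd.DataFrame({"rank": rank}, index=grouped.columns)
    return FeatureTable(grouped, scale=table.scale, feature_meta=meta,
                        zero_samples=table.zero_samples)


def collapse_patient_means(table: FeatureTable, meta: SampleMetadata,
                           patients: list[str] | None = None) -> tuple[FeatureTable, SampleMetadata]:
    """Average technical replicate samples of a patient into one profile.

    Optional cohort fix for pooled replicate sequencing; off the default
    path.  Only patients listed in *patients* (default: all with > 1
    sample of the same diagnosis) are collapsed; the collapsed sample id is
    ``{patient}:{diagnosis}``.
    """
    meta.validate_against(table)
    md = meta.data.loc[table.sample_ids]
    key = md["patient_id"].astype(str) + ":" + md["diagnosis"].astype(str)
    if patients is not None:
        keep_own = ~md["patient_id"].isin(patients)
        key = key.where(~keep_own, pd.Series(table.sample_ids, index=key.index))
    data = table.data.groupby(key.values, sort=True).mean()
    new_md = md.assign(_k=key.values).groupby("_k", sort=True).first()
    new_md.index.name = "sample_id"
    ft = FeatureTable(data, scale=table.scale, feature_meta=table.feature_meta)
    return ft, SampleMetadata(new_md)
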