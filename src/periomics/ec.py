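"""Enzyme Commission (EC) feature construction from gene-level transcript counts.

Metatranscriptome reads counted per gene are summed into functional
features keyed by EC number.  A gene annotated with several EC numbers is
counted at the deepest hierarchy level at which its codes still agree
(their longest common prefix); genes whose codes already differ within the
first two fields are pooled into an ``Unknown`` bucket so that no read is
ever dropped and totals are conserved.  A taxon-resolved variant keeps the
most abundant EC-annotated genes and distributes each EC's expression over
the contributing taxa (class or genus level), yielding a
sample x EC x taxon tensor for pathway-ecology analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from periomics.tables import FeatureTable, TableError


class EcError(ValueError):
    """Raised for malformed EC codes or annotations."""


@dataclass(frozen=True)
class EcKey:
    """An EC code truncated to ``level`` fields, or the ``Unknown`` sentinel."""

    code: str
    level: int | None

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.code


UNKNOWN = EcKey("Unknown", None)

#: minimum depth of agreement between a gene's EC codes; codes diverging
#: within the first two fields send the gene to the Unknown bucket
MIN_COMMON_LEVEL = 2


def parse_ec(code: str) -> tuple[int, ...]:
    """Parse ``"1.2.3.4"``-style codes into 1-4 integer fields."""
    parts = str(code).strip().split(".")
    if not 1 <= len(parts) <= 4:
        raise EcError(f"EC code {code!r} has {len(parts)} fields (expected 1-4)")
    try:
        return tuple(int(p) for p in parts)
    except ValueError as exc:
        raise EcError(f"unparseable EC code {code!r}") from exc


def collapse_ec(ecs) -> EcKey:
    """Collapse a set of EC codes to their longest common prefix.

    Returns the prefix as an :class:`EcKey` when at least the first two
    fields agree across all codes, otherwise :data:`UNKNOWN`.  Order- and
    multiplicity-insensitive; idempotent on its own (single-code) output.
    """
    parsed = {parse_ec(e) for e in ecs}
    if not parsed:
        raise EcError("collapse_ec needs a non-empty set of EC codes")
    first = next(iter(parsed))
    depth = 0
    for i in range(min(len(p) for p in parsed)):
        if all(p[i] == first[i] for p in parsed):
            depth = i + 1
        else:
            break
    if depth < MIN_COMMON_LEVEL:
        return UNKNOWN
    code = ".".join(str(f) for f in first[:depth])
    return EcKey(code, depth)


def truncate_key(key: EcKey, level: int) -> EcKey:
    """Re-truncate a key to *level* fields; coarser keys pass through."""
    if key.level is None or key.level <= level:
        return key
    fields = key.code.split(".")[:level]
    return EcKey(".".join(fields), level)


# ---------------------------------------------------------------------------
# Annotations

ANNOTATION_COLUMNS = ("gene_id", "ec_codes", "class", "genus")


def read_annotations(path) -> pd.DataFrame:
    """Read a gene annotation TSV: gene_id, comma-separated EC list, lineage.

    An empty EC cell means the gene is unannotated (counted as Unknown and
    excluded from taxon-resolved profiling).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise EcError(f"annotation file lacks columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise EcError(f"duplicate gene annotation {dup!r}")
    return df.set_index("gene_id")


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.rename_axis("gene_id").to_csv(path, sep="\t")


def _gene_keys(gene_ids, ann: pd.DataFrame) -> list[EcKey]:
    keys = []
    for g in gene_ids:
        if g not in ann.index:
            raise EcError(f"gene {g!r} has no annotation record")
        raw = str(ann.at[g, "ec_codes"]).strip()
        codes = [c for c in raw.split(",") if c.strip()]
        keys.append(collapse_ec(codes) if codes else UNKNOWN)
    return keys


def aggregate_to_ec(genes: FeatureTable, ann: pd.DataFrame, level: int = 4,
                    include_unknown: bool = True) -> FeatureTable:
    """Sum gene counts into EC features at the requested hierarchy level.

    Each gene's EC set is first collapsed (see :func:`collapse_ec`); keys
    deeper than *level* are truncated to it, keys coarser than *level*
    remain at their own depth, and unannotated/divergent genes land in
    ``Unknown``.  Grand totals are conserved exactly when
    ``include_unknown`` is true.
    """
    if not 1 <= level <= 4:
        raise EcError(f"level must be 1..4, got {level}")
    keys = [truncate_key(k, level) for k in _gene_keys(genes.feature_ids, ann)]
    labels = [k.code for k in keys]
    grouped = genes.data.T.groupby(np.asarray(labels), sort=True).sum().T
    if not include_unknown and "Unknown" in grouped.columns:
        grouped = grouped.drop(columns="Unknown")
    lev = {k.code: (0 if k.level is None else k.level) for k in keys}
    meta = pd.DataFrame(
        {"rank": [("Unknown" if c == "Unknown" else f"EC{lev[c]}") for c in grouped.columns],
         "source": "RNA"},
        index=grouped.columns,
    )
    return FeatureTable(grouped, scale=genes.scale, feature_meta=meta,
                        zero_samples=genes.zero_samples)


# ---------------------------------------------------------------------------
# Taxon-resolved tensor


@dataclass
class EcTaxonTensor:
    """Dense sample x EC x taxon array of (normalised) expression values."""

    values: np.ndarray  # shape (n_samples, n_ecs, n_taxa)
    sample_ids: list[str]
    ec_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        expect = (len(self.sample_ids), len(self.ec_ids), len(self.taxon_ids))
        if self.values.shape != expect:
            raise EcError(f"tensor shape {self.values.shape} != ids {expect}")
        if (self.values < 0).any():
            raise EcError("tensor contains negative values")

    def marginal_ec(self, scale: str = "relative") -> FeatureTable:
        """Sum over taxa -> samples x EC table."""
        data = pd.DataFrame(self.values.sum(axis=2), index=self.sample_ids,
                            columns=self.ec_ids)
        zero = tuple(data.index[data.sum(axis=1) == 0])
        return FeatureTable(data, scale=scale, zero_samples=zero)

    def taxon_totals(self) -> pd.DataFrame:
        """Per-sample total expression of each taxon (samples x taxa)."""
        return pd.DataFrame(self.values.sum(axis=1), index=self.sample_ids,
                            columns=self.taxon_ids)


def taxon_resolved_ec(genes: FeatureTable, ann: pd.DataFrame,
                      taxon_rank: str = "class", top_n: int = 1_000_000,
                      level: int = 4) -> EcTaxonTensor:
    """Build a per-sample-normalised sample x EC x taxon expression tensor.

    Mirrors taxon-of-function profiling of a metatranscriptome: only the
    ``top_n`` most abundant EC-annotated genes are retained (hypothetical /
    EC-less genes are dropped first), counts are normalised per sample by
    the retained total, and then aggregated by (EC key, taxon label).
    Summing the tensor over taxa reproduces the EC table restricted to the
    retained genes.
    """
    if taxon_rank not in ("class", "genus"):
        raise EcError(f"taxon_rank must be class or genus, got {taxon_rank!r}")
    keys = _gene_keys(genes.feature_ids, ann)
    annotated = [g for g, k in zip(genes.feature_ids, keys) if k is not UNKNOWN]
    if not annotated:
        raise EcError("no EC-annotated genes to profile")
    totals = genes.data[annotated].sum(axis=0)
    top_n = min(top_n, len(annotated))
    keep = list(totals.sort_values(ascending=False, kind="stable").index[:top_n])
    sub = genes.data[keep].to_numpy(dtype=float)
    denom = sub.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    sub = sub / denom

    key_by_gene = dict(zip(genes.feature_ids, keys))
    ec_labels = [truncate_key(key_by_gene[g], level).code for g in keep]
    tax_labels = [str(ann.at[g, taxon_rank]) or "unclassified" for g in keep]
    ec_ids = sorted(set(ec_labels))
    taxon_ids = sorted(set(tax_labels))
    e_idx = {e: i for i, e in enumerate(ec_ids)}
    t_idx = {t: i for i, t in enumerate(taxon_ids)}
    tensor = np.zeros((genes.n_samples, len(ec_ids), len(taxon_ids)))
    for j, (e, t) in enumerate(zip(ec_labels, tax_labels)):
        tensor[:, e_idx[e], t_idx[t]] += sub[:, j]
    return EcTaxonTensor(tensor, genes.sample_ids, ec_ids, taxon_ids)
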