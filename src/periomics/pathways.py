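"""Curated amino-acid metabolic pathway readouts.

A pathway definition names an amino acid, a direction (anabolic =
biosynthesis, catabolic = utilisation) and the set of fully specified
(EC4) enzyme codes that constitute the pathway.  Against a per-sample
normalised EC expression table, three readouts summarise the confidence
and extent of pathway expression:

1. *abundance* — the pathway's share of total community expression;
2. *coverage* — the fraction of pathway enzymes whose expression reaches
   a global threshold, the median over all (EC, sample) entries of the
   full table (zeros included by default);
3. *expressing-taxa proportion* — among taxa detected in a sample, the
   fraction transcribing at least one pathway enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from periomics.ec import EcTaxonTensor, parse_ec
from periomics.tables import FeatureTable

DIRECTIONS = ("anabolic", "catabolic")


class PathwayError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayDefinition:
    """An amino-acid pathway as an ordered set of EC4 codes."""

    pathway_id: str
    amino_acid: str
    direction: str
    ec_set: tuple[str, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise PathwayError(f"direction must be one of {DIRECTIONS}, "
                               f"got {self.direction!r}")
        if not self.ec_set:
            raise PathwayError(f"pathway {self.pathway_id!r} has an empty EC set")
        for ec in self.ec_set:
            parse_ec(ec)


def load_pathways(path) -> list[PathwayDefinition]:
    """Read pathway definitions from TSV.

    Columns: pathway_id, amino_acid, direction, ec_list (comma-separated
    EC codes), optional note.  Duplicate pathway ids and duplicate
    (amino_acid, direction) pairs are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"pathway_id", "amino_acid", "direction", "ec_list"}
    missing = required - set(df.columns)
    if missing:
        raise PathwayError(f"pathway file lacks columns {sorted(missing)}")
    if df["pathway_id"].duplicated().any():
        dup = df.loc[df["pathway_id"].duplicated(), "pathway_id"].iloc[0]
        raise PathwayError(f"duplicate pathway_id {dup!r}")
    pathways = []
    seen = set()
    for _, row in df.iterrows():
        key = (row["amino_acid"], row["direction"])
        if key in seen:
            raise PathwayError(f"duplicate pathway for {key}")
        seen.add(key)
        ecs = tuple(e.strip() for e in row["ec_list"].split(",") if e.strip())
        pathways.append(PathwayDefinition(
            pathway_id=row["pathway_id"], amino_acid=row["amino_acid"],
            direction=row["direction"], ec_set=ecs,
            note=row.get("note", "") if isinstance(row.get("note", ""), str) else ""))
    return pathways


def write_pathways(pathways: list[PathwayDefinition], path) -> None:
    pd.DataFrame([{
        "pathway_id": p.pathway_id, "amino_acid": p.amino_acid,
        "direction": p.direction, "ec_list": ",".join(p.ec_set),
        "note": p.note,
    } for p in pathways]).to_csv(path, sep="\t", index=False)


def _present_ecs(table: FeatureTable, pw: PathwayDefinition,
                 warn: bool = True) -> list[str]:
    present = [e for e in pw.ec_set if e in table.data.columns]
    if warn and len(present) < len(pw.ec_set):
        absent = sorted(set(pw.ec_set) - set(present))
        warnings.warn(f"pathway {pw.pathway_id}: {len(absent)} EC(s) absent "
                      f"from the table (e.g. {absent[:3]})", stacklevel=3)
    return present


def pathway_abundance(ec_table: FeatureTable, pw: PathwayDefinition) -> pd.Series:
    """Per-sample share of total expression carried by the pathway's ECs."""
    if ec_table.scale != "relative":
        raise PathwayError("pathway_abundance expects a relative-scale EC table")
    present = _present_ecs(ec_table, pw, warn=False)
    if not present:
        return pd.Series(0.0, index=ec_table.data.index, name=pw.pathway_id)
    return ec_table.data[present].sum(axis=1).rename(pw.pathway_id)


def median_threshold(ec_table: FeatureTable, include_zeros: bool = True) -> float:
    """Global median over every (EC, sample) entry of the full table."""
    flat = ec_table.values.ravel()
    if not include_zeros:
        flat = flat[flat > 0]
    if flat.size == 0:
        raise PathwayError("cannot take a median of an empty table")
    return float(np.median(flat))


def pathway_coverage(ec_table: FeatureTable, pw: PathwayDefinition,
                     include_zeros: bool = True) -> pd.Series:
    """Fraction of the pathway's ECs at or above the global median threshold.

    The threshold is a single number for the whole table; ECs absent from
    the table count as not covered.
    """
    tau = median_threshold(ec_table, include_zeros)
    present = _present_ecs(ec_table, pw)
    size = len(pw.ec_set)
    if not present:
        return pd.Series(0.0, index=ec_table.data.index, name=pw.pathway_id)
    hits = (ec_table.data[present] >= tau).sum(axis=1)
    return (hits / size).rename(pw.pathway_id)


def expressing_taxa_proportion(tensor: EcTaxonTensor, pw: PathwayDefinition,
                               min_count: float = 1.0,
                               detected_only: bool = True) -> pd.Series:
    """Per-sample proportion of taxa expressing at least one pathway EC.

    A taxon "expresses" the pathway in a sample when its counts summed
    over the pathway's ECs reach ``min_count``.  The denominator is the
    number of taxa detected in the sample (any nonzero expression), or all
    taxa when ``detected_only`` is false.
    """
    cols = [tensor.ec_ids.index(e) for e in pw.ec_set if e in tensor.ec_ids]
    n_s, _, n_t = tensor.values.shape
    expressing = (tensor.values[:, cols, :].sum(axis=1) >= min_count
                  if cols else np.zeros((n_s, n_t), dtype=bool))
    if detected_only:
        detected = tensor.values.sum(axis=1) > 0
        denom = detected.sum(axis=1).astype(float)
    else:
        denom = np.full(n_s, float(n_t))
    denom[denom == 0] = np.nan
    prop = expressing.sum(axis=1) / denom
    return pd.Series(np.nan_to_num(prop), index=tensor.sample_ids,
                     name=pw.pathway_id)


def pathway_matrix(ec_table: FeatureTable,
                   pathways: list[PathwayDefinition]) -> FeatureTable:
    """Samples x pathways abundance table for ordination and group tests."""
    if not pathways:
        warnings.warn("empty pathway list -> empty pathway matrix", stacklevel=2)
        data = pd.DataFrame(index=ec_table.data.index)
        return FeatureTable(data, scale="relative",
                            zero_samples=tuple(ec_table.data.index))
    cols = {p.pathway_id: pathway_abundance(ec_table, p) for p in pathways}
    data = pd.DataFrame(cols, index=ec_table.data.index)
    zero = tuple(data.index[data.sum(axis=1) == 0])
    meta = pd.DataFrame({
        "amino_acid": [p.amino_acid for p in pathways],
        "direction": [p.direction for p in pathways],
    }, index=[p.pathway_id for p in pathways])
    return FeatureTable(data, scale="counts", feature_meta=meta, zero_samples=zero)
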