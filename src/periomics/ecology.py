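"""Taxon roles in the amino-acid economy of a biofilm.

For each taxon and amino-acid pathway the *specific-to-total activity
fold* compares the taxon's share of the pathway's expression with its
share of whole-community expression:

    phi = log2(specific_share / total_share)

A strongly positive anabolic phi marks a producer (high anabolism), a
strongly negative anabolic phi a taxon that barely synthesises the amino
acid itself (low anabolism, candidate auxotroph), and a strongly positive
catabolic phi a heavy consumer (high catabolism).  An edge is drawn in
the taxon-amino-acid network when |phi| exceeds a threshold, strictly
greater than 1.5 by default.  Low catabolism is deliberately not a role.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from periomics.ec import EcTaxonTensor
from periomics.pathways import PathwayDefinition
from periomics.tables import SampleMetadata

ROLES = ("low-anabolism", "high-anabolism", "high-catabolism")


@dataclass(frozen=True)
class ActivityFold:
    """phi for one (taxon, amino acid, direction) within one scope."""

    taxon: str
    amino_acid: str
    direction: str
    scope: str                 # "pooled" or a diagnosis label
    specific_share: float
    total_share: float
    phi: float                 # log2(specific/total); nan when undefined
    defined: bool


def _scope_masks(tensor: EcTaxonTensor, group_by: str,
                 metadata: SampleMetadata | None) -> dict[str, np.ndarray]:
    if group_by == "pooled":
        return {"pooled": np.ones(len(tensor.sample_ids), dtype=bool)}
    if group_by != "diagnosis":
        raise ValueError(f"group_by must be pooled or diagnosis, got {group_by!r}")
    if metadata is None:
        raise ValueError("diagnosis scoping needs sample metadata")
    diag = metadata.diagnosis(tensor.sample_ids)
    return {str(g): (diag == g).to_numpy() for g in sorted(diag.unique())}


def activity_folds(tensor: EcTaxonTensor, pathways: list[PathwayDefinition],
                   group_by: str = "diagnosis",
                   metadata: SampleMetadata | None = None) -> list[ActivityFold]:
    """Specific-to-total activity folds per taxon, amino acid and direction.

    Shares are computed on expression summed over the samples of a scope
    (pooled, or each diagnosis group): ``specific_share`` is the taxon's
    fraction of the pathway's expression, ``total_share`` its fraction of
    all expression.  phi is undefined (flagged, nan) when either share is
    zero — no pseudocount is added.
    """
    masks = _scope_masks(tensor, group_by, metadata)
    values = tensor.values
    folds: list[ActivityFold] = []
    for scope, mask in masks.items():
        sub = values[mask]                      # samples x ec x taxon
        total_by_taxon = sub.sum(axis=(0, 1))   # taxa
        grand = total_by_taxon.sum()
        for pw in pathways:
            cols = [tensor.ec_ids.index(e) for e in pw.ec_set
                    if e in tensor.ec_ids]
            pw_by_taxon = (sub[:, cols, :].sum(axis=(0, 1))
                           if cols else np.zeros_like(total_by_taxon))
            pw_total = pw_by_taxon.sum()
            for t, taxon in enumerate(tensor.taxon_ids):
                specific = pw_by_taxon[t] / pw_total if pw_total > 0 else 0.0
                total = total_by_taxon[t] / grand if grand > 0 else 0.0
                defined = specific > 0 and total > 0
                phi = float(np.log2(specific / total)) if defined else float("nan")
                folds.append(ActivityFold(
                    taxon=taxon, amino_acid=pw.amino_acid,
                    direction=pw.direction, scope=scope,
                    specific_share=float(specific), total_share=float(total),
                    phi=phi, defined=defined))
    return folds


@dataclass
class EcologyNetwork:
    """Bipartite taxon-amino-acid role graph as an edge table."""

    edges: pd.DataFrame      # taxon, amino_acid, role, phi, scope
    threshold: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, e in self.edges.iterrows():
            g.add_node(e["taxon"], kind="taxon")
            g.add_node(e["amino_acid"], kind="amino_acid")
            g.add_edge(e["taxon"], e["amino_acid"], role=e["role"],
                       phi=float(e["phi"]), scope=e["scope"])
        return g


EDGE_COLUMNS = ["taxon", "amino_acid", "role", "phi", "scope"]


def classify_roles(folds: list[ActivityFold],
                   threshold: float = 1.5) -> EcologyNetwork:
    """Assign ecological roles from activity folds.

    Strictly-greater rule: anabolic phi > threshold -> high-anabolism,
    anabolic phi < -threshold -> low-anabolism, catabolic phi > threshold
    -> high-catabolism.  Undefined folds never produce an edge.
    """
    rows = []
    for f in folds:
        if not f.defined:
            continue
        role = None
        if f.direction == "anabolic":
            if f.phi > threshold:
                role = "high-anabolism"
            elif f.phi < -threshold:
                role = "low-anabolism"
        elif f.direction == "catabolic" and f.phi > threshold:
            role = "high-catabolism"
        if role is not None:
            rows.append({"taxon": f.taxon, "amino_acid": f.amino_acid,
                         "role": role, "phi": f.phi, "scope": f.scope})
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return EcologyNetwork(edges=edges, threshold=threshold)


def export_network(net: EcologyNetwork, path, fmt: str = "tsv") -> None:
    """Write the network as an edge-list TSV or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.graph(), path)
    else:
        raise ValueError(f"unknown format {fmt!r} (tsv or graphml)")


def read_network(path, threshold: float = 1.5) -> EcologyNetwork:
    """Read back an edge-list TSV written by :func:`export_network`."""
    edges = pd.read_csv(path, sep="\t", dtype={"phi": float})
    if edges.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    return EcologyNetwork(edges=edges[EDGE_COLUMNS], threshold=threshold)
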