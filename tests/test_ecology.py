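"""Specific-to-total activity folds, role classification, network export."""

import numpy as np
import pandas as pd
import pytest

import periomics as po
from periomics.ec import EcTaxonTensor
from periomics.ecology import ActivityFold


def make_tensor(values, ecs, taxa, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return EcTaxonTensor(values, samples, ecs, taxa)


def simple_pathways():
    return [po.PathwayDefinition("lys_cat", "lysine", "catabolic",
                                 ("1.1.1.1",)),
            po.PathwayDefinition("lys_an", "lysine", "anabolic",
                                 ("2.2.2.2",))]


class TestActivityFolds:
    def test_equal_shares_phi_zero(self):
        # one taxon contributes the same fraction of pathway and biofilm
        values = np.zeros((1, 2, 2))
        values[0, 0] = [1, 3]   # pathway EC: shares 0.25 / 0.75
        values[0, 1] = [1, 3]   # rest mirrors the same split
        t = make_tensor(values, ["1.1.1.1", "9.9.9.9"], ["tA", "tB"])
        folds = po.activity_folds(t, simple_pathways()[:1], group_by="pooled")
        fa = [f for f in folds if f.taxon == "tA"][0]
        assert fa.phi == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_fold(self):
        # taxon tA: 35% of the pathway but only 10% of the biofilm
        values = np.zeros((1, 2, 2))
        values[0, 0] = [35, 65]
        values[0, 1] = [65, 835]
        t = make_tensor(values, ["1.1.1.1", "9.9.9.9"], ["tA", "tB"])
        folds = po.activity_folds(t, simple_pathways()[:1], group_by="pooled")
        fa = [f for f in folds if f.taxon == "tA"][0]
        assert fa.specific_share == pytest.approx(0.35)
        assert fa.total_share == pytest.approx(0.10)
        assert fa.phi == pytest.approx(np.log2(3.5), abs=1e-9)

    def test_absent_taxon_flagged_not_crashed(self):
        values = np.zeros((1, 2, 2))
        values[0, 0] = [4, 0]    # tB absent from the pathway
        values[0, 1] = [4, 8]
        t = make_tensor(values, ["1.1.1.1", "9.9.9.9"], ["tA", "tB"])
        folds = po.activity_folds(t, simple_pathways()[:1], group_by="pooled")
        fb = [f for f in folds if f.taxon == "tB"][0]
        assert not fb.defined
        assert np.isnan(fb.phi)

    def test_specific_shares_sum_to_one(self, cohort):
        folds = po.activity_folds(cohort["tensor"], cohort["pathways"],
                                  group_by="diagnosis",
                                  metadata=cohort["meta"])
        sums: dict = {}
        for f in folds:
            sums.setdefault((f.amino_acid, f.direction, f.scope), 0.0)
            sums[(f.amino_acid, f.direction, f.scope)] += f.specific_share
        for key, total in sums.items():
            if total > 0:  # pathways expressed in the scope
                assert total == pytest.approx(1.0, abs=1e-9)


class TestClassifyRoles:
    def fold(self, phi, direction="anabolic", taxon="tA", aa="lysine"):
        return ActivityFold(taxon=taxon, amino_acid=aa, direction=direction,
                            scope="pooled", specific_share=0.1,
                            total_share=0.1, phi=phi, defined=True)

    def test_three_roles_and_strict_boundary(self):
        folds = [self.fold(1.807, "anabolic"),              # high-anabolism
                 self.fold(-1.6, "anabolic", taxon="tB"),   # low-anabolism
                 self.fold(2.0, "catabolic", taxon="tC"),   # high-catabolism
                 self.fold(1.5, "anabolic", taxon="tD"),    # exactly at cutoff
                 self.fold(-1.5, "catabolic", taxon="tE")]  # low catabolism: no role
        net = po.classify_roles(folds, threshold=1.5)
        roles = dict(zip(net.edges["taxon"], net.edges["role"]))
        assert roles == {"tA": "high-anabolism", "tB": "low-anabolism",
                         "tC": "high-catabolism"}

    def test_undefined_folds_never_edge(self):
        f = ActivityFold("tA", "lysine", "anabolic", "pooled", 0.0, 0.1,
                         float("nan"), False)
        net = po.classify_roles([f])
        assert len(net.edges) == 0

    def test_planted_roles_recovered(self, cohort):
        folds = po.activity_folds(cohort["tensor"], cohort["pathways"],
                                  group_by="diagnosis",
                                  metadata=cohort["meta"])
        net = po.classify_roles(folds)
        edges = set(zip(net.edges["taxon"], net.edges["amino_acid"],
                        net.edges["role"]))
        rep = po.truth_check(cohort["truth"], role_edges=edges)["roles"]
        assert rep["recall"] == 1.0


class TestExportNetwork:
    def net(self):
        edges = pd.DataFrame([
            {"taxon": "tA", "amino_acid": "lysine", "role": "high-catabolism",
             "phi": 2.1, "scope": "peri-implantitis"},
            {"taxon": "tB", "amino_acid": "histidine", "role": "high-anabolism",
             "phi": 1.9, "scope": "healthy"},
            {"taxon": "tB", "amino_acid": "lysine", "role": "low-anabolism",
             "phi": -1.8, "scope": "healthy"},
        ])
        return po.EcologyNetwork(edges=edges, threshold=1.5)

    def test_tsv_round_trip(self, tmp_path):
        net = self.net()
        path = tmp_path / "net.tsv"
        po.export_network(net, path)
        assert len(path.read_text().strip().splitlines()) == 4  # header + 3
        back = po.read_network(path)
        pd.testing.assert_frame_equal(back.edges, net.edges)

    def test_graphml_is_bipartite_with_attributes(self, tmp_path):
        import networkx as nx
        net = self.net()
        path = tmp_path / "net.graphml"
        po.export_network(net, path, fmt="graphml")
        g = nx.read_graphml(path)
        assert g.nodes["tA"]["kind"] == "taxon"
        assert g.nodes["lysine"]["kind"] == "amino_acid"
        assert g.edges["tA", "lysine"]["role"] == "high-catabolism"

    def test_empty_network_valid_file(self, tmp_path):
        empty = po.EcologyNetwork(
            edges=pd.DataFrame(columns=["taxon", "amino_acid", "role",
                                        "phi", "scope"]), threshold=1.5)
        path = tmp_path / "empty.tsv"
        po.export_network(empty, path)
        back = po.read_network(path)
        assert len(back.edges) == 0
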