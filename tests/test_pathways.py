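"""Amino-acid pathway definitions and the three expression readouts."""

import numpy as np
import pandas as pd
import pytest

import periomics as po
from periomics.ec import EcTaxonTensor
from periomics.pathways import PathwayError, median_threshold, write_pathways

from conftest import toy_table


def pw(pid="lysine_catabolic", aa="lysine", direction="catabolic",
       ecs=("1.1.1.1", "2.2.2.2", "3.3.3.3")):
    return po.PathwayDefinition(pathway_id=pid, amino_acid=aa,
                                direction=direction, ec_set=tuple(ecs))


class TestLoadPathways:
    def test_round_trip(self, tmp_path):
        pws = [pw(), pw("lysine_anabolic", "lysine", "anabolic",
                        ("4.4.4.4", "5.5.5.5"))]
        path = tmp_path / "pw.tsv"
        write_pathways(pws, path)
        back = po.load_pathways(path)
        assert len(back) == 2
        assert back[0].ec_set == pws[0].ec_set
        assert back[1].direction == "anabolic"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "pw.tsv"
        path.write_text("pathway_id\tamino_acid\tdirection\tec_list\n"
                        "p1\tlysine\tanabolic\t1.1.1.1\n"
                        "p1\tlysine\tcatabolic\t2.2.2.2\n")
        with pytest.raises(PathwayError, match="duplicate"):
            po.load_pathways(path)

    def test_empty_ec_set_rejected(self, tmp_path):
        path = tmp_path / "pw.tsv"
        path.write_text("pathway_id\tamino_acid\tdirection\tec_list\n"
                        "p1\tlysine\tanabolic\t\n")
        with pytest.raises(PathwayError, match="empty EC set"):
            po.load_pathways(path)


class TestAbundance:
    def test_absent_ecs_zero_and_full_table_one(self):
        rel = po.to_relative(toy_table([[1, 2, 1]],
                                       feature_ids=["1.1.1.1", "2.2.2.2",
                                                    "3.3.3.3"]))
        assert po.pathway_abundance(rel, pw(ecs=("9.9.9.9",))).iloc[0] == 0.0
        assert po.pathway_abundance(rel, pw()).iloc[0] == pytest.approx(1.0)

    def test_hand_summed_toy(self):
        values = np.array([[10, 20, 30, 40.0],
                           [5, 5, 5, 85.0],
                           [0, 50, 25, 25.0],
                           [1, 1, 1, 97.0]])
        rel = po.to_relative(toy_table(
            values, feature_ids=["1.1.1.1", "2.2.2.2", "3.3.3.3", "7.7.7.7"]))
        got = po.pathway_abundance(rel, pw())
        expect = values[:, :3].sum(axis=1) / values.sum(axis=1)
        np.testing.assert_allclose(got.to_numpy(), expect)

    def test_nested_pathway_monotone(self):
        rng = np.random.default_rng(0)
        ecs = [f"1.1.{i}.1" for i in range(1, 7)]
        rel = po.to_relative(toy_table(rng.random((5, 6)), feature_ids=ecs))
        small = po.pathway_abundance(rel, pw(ecs=tuple(ecs[:2])))
        big = po.pathway_abundance(rel, pw(ecs=tuple(ecs[:5])))
        assert (small <= big + 1e-12).all()


class TestCoverage:
    def test_brute_force_on_toy_table(self):
        rng = np.random.default_rng(1)
        values = rng.random((4, 4))
        ecs = ["1.1.1.1", "2.2.2.2", "3.3.3.3", "4.4.4.4"]
        t = po.FeatureTable(pd.DataFrame(
            values / values.sum(axis=1, keepdims=True),
            index=list("abcd"), columns=ecs), scale="relative")
        p = pw(ecs=("1.1.1.1", "3.3.3.3"))
        got = po.pathway_coverage(t, p)
        tau = np.median(t.values.ravel())
        for i, sid in enumerate("abcd"):
            expect = np.mean([t.values[i, 0] >= tau, t.values[i, 2] >= tau])
            assert got[sid] == pytest.approx(expect)

    def test_all_above_threshold_full_coverage(self):
        t = po.FeatureTable(pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5]], index=["a", "b"],
            columns=["1.1.1.1", "2.2.2.2"]), scale="relative")
        assert (po.pathway_coverage(t, pw(ecs=("1.1.1.1", "2.2.2.2"))) == 1).all()

    def test_outside_ecs_act_only_through_tau(self):
        # swapping values among non-pathway ECs leaves tau (a global
        # order statistic) unchanged, hence coverage unchanged
        rng = np.random.default_rng(2)
        values = rng.random((3, 6))
        ecs = [f"{i}.1.1.1" for i in range(1, 7)]
        t1 = toy_table(values, feature_ids=ecs, scale="counts")
        shuffled = values.copy()
        shuffled[:, 3:] = shuffled[:, [5, 3, 4]]
        t2 = toy_table(shuffled, feature_ids=ecs, scale="counts")
        p = pw(ecs=("1.1.1.1", "2.1.1.1"))
        r1 = po.to_relative(t1)
        r2 = po.to_relative(t2)
        assert median_threshold(r1) == pytest.approx(median_threshold(r2))
        pd.testing.assert_series_equal(po.pathway_coverage(r1, p),
                                       po.pathway_coverage(r2, p))


class TestExpressingTaxa:
    def tensor(self, values, ecs, taxa):
        return EcTaxonTensor(np.asarray(values, dtype=float),
                             [f"s{i}" for i in range(len(values))], ecs, taxa)

    def test_single_expressing_taxon(self):
        t = self.tensor([[[5.0]]], ["1.1.1.1"], ["tA"])
        assert po.expressing_taxa_proportion(t, pw(ecs=("1.1.1.1",))).iloc[0] == 1.0

    def test_two_of_four_detected(self):
        values = np.zeros((1, 2, 4))
        values[0, 0, :] = [3, 2, 0.5, 0]   # pathway EC; taxon 3 below min_count
        values[0, 1, :] = [1, 1, 1, 0]     # other EC keeps taxa 0-2 detected
        t = self.tensor(values, ["1.1.1.1", "9.9.9.9"], list("abcd"))
        got = po.expressing_taxa_proportion(t, pw(ecs=("1.1.1.1",)), min_count=1)
        assert got.iloc[0] == pytest.approx(2 / 3)  # 2 of 3 detected taxa

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 4, (5, 6, 4)).astype(float)
        ecs = [f"{i}.1.1.1" for i in range(1, 7)]
        t = self.tensor(values, ecs, list("wxyz"))
        p = pw(ecs=(ecs[0], ecs[2]))
        got = po.expressing_taxa_proportion(t, p, min_count=2)
        for s in range(5):
            detected = [k for k in range(4) if values[s, :, k].sum() > 0]
            expressing = [k for k in detected
                          if values[s, 0, k] + values[s, 2, k] >= 2]
            assert got.iloc[s] == pytest.approx(len(expressing) / len(detected))


class TestPathwayMatrix:
    def test_partition_rows_sum_to_one(self):
        ecs = [f"{i}.1.1.1" for i in range(1, 7)]
        rel = po.to_relative(toy_table(np.arange(1, 13).reshape(2, 6),
                                       feature_ids=ecs))
        pws = [pw("a_an", "alanine", "anabolic", tuple(ecs[:3])),
               pw("a_cat", "alanine", "catabolic", tuple(ecs[3:]))]
        mat = po.pathway_matrix(rel, pws)
        np.testing.assert_allclose(mat.values.sum(axis=1), 1.0)

    def test_empty_pathway_list_warns(self):
        rel = po.to_relative(toy_table([[1, 1]]))
        with pytest.warns(UserWarning, match="empty pathway list"):
            mat = po.pathway_matrix(rel, [])
        assert mat.n_features == 0

    def test_planted_shift_separates_groups(self, cohort):
        ec4 = po.aggregate_to_ec(cohort["rna"], cohort["ann"], level=4)
        rel = po.to_relative(ec4)
        mat = po.pathway_matrix(rel, cohort["pathways"])
        dm = po.bray_curtis(po.log1p_transform(po.to_relative(mat)))
        res = po.permanova(dm, cohort["meta"].diagnosis(list(dm.ids)),
                           n_perm=999, seed=0)
        assert res.p_value < 0.01

    def test_readouts_invariant_to_column_order(self):
        rng = np.random.default_rng(4)
        ecs = [f"{i}.2.3.4" for i in range(1, 9)]
        values = rng.random((4, 8))
        rel1 = po.to_relative(toy_table(values, feature_ids=ecs))
        perm = rng.permutation(8)
        rel2 = po.to_relative(toy_table(values[:, perm],
                                        feature_ids=[ecs[j] for j in perm]))
        p = pw(ecs=(ecs[0], ecs[3], ecs[5]))
        pd.testing.assert_series_equal(po.pathway_abundance(rel1, p),
                                       po.pathway_abundance(rel2, p))
        pd.testing.assert_series_equal(po.pathway_coverage(rel1, p),
                                       po.pathway_coverage(rel2, p))
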