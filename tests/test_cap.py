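"""CAP: canonical correlations, LOO allocation, projection, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import pearsonr, rankdata
from skbio import DistanceMatrix

import periomics as po
from periomics.cap import load_model, save_model
from periomics.ordination import gower_center


def euclid_dm(points, prefix="s"):
    ids = [f"{prefix}{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


def separable(n_per=8, sep=50.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, 3))
    b = rng.normal(0, 1, (n_per, 3))
    b[:, 0] += sep
    groups = ["healthy"] * n_per + ["peri-implantitis"] * n_per
    return np.vstack([a, b]), groups


def cca_first_rho2(x, y):
    """Independent canonical-correlation oracle via QR + SVD."""
    x = x - x.mean(axis=0)
    y = np.atleast_2d(y).T if np.ndim(y) == 1 else y
    y = y - y.mean(axis=0)
    qx, _ = np.linalg.qr(x)
    qy, _ = np.linalg.qr(y)
    s = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return s[0] ** 2


class TestCapFit:
    def test_separable_groups_fully_resolved(self):
        pts, groups = separable()
        model = po.cap_fit(euclid_dm(pts), groups, m=1)
        assert model.delta_sq[0] >= 0.99
        assert model.loo_success == 1.0

    def test_delta_sq_matches_cca_oracle(self):
        pts, groups = separable(sep=2.0, seed=3)
        dm = euclid_dm(pts)
        m = 3
        model = po.cap_fit(dm, groups, m=m)
        vals, vecs = np.linalg.eigh(gower_center(dm.data))
        order = np.argsort(vals)[::-1]
        q_m = vecs[:, order][:, :m]
        y = np.array([g == "healthy" for g in groups], dtype=float)
        rho2 = cca_first_rho2(q_m, y)
        assert model.delta_sq[0] == pytest.approx(rho2, abs=1e-8)

    def test_orientation_puts_healthy_negative(self):
        pts, groups = separable(seed=5)
        model = po.cap_fit(euclid_dm(pts), groups, m=2)
        scores = model.canonical_scores.iloc[:, 0]
        healthy = [g == "healthy" for g in groups]
        assert scores[healthy].mean() < 0 < scores[np.logical_not(healthy)].mean()

    def test_m_selection_prefers_smallest_tie(self):
        pts, groups = separable()
        model = po.cap_fit(euclid_dm(pts), groups, m_grid=range(1, 6))
        assert model.m == 1  # already perfect at m=1; ties go small
        assert model.m_grid_success[1] == 1.0

    def test_single_group_rejected(self):
        pts, _ = separable(n_per=4)
        with pytest.raises(ValueError, match="2 groups"):
            po.cap_fit(euclid_dm(pts), ["x"] * 8)

    def test_m_exceeding_positive_axes_rejected(self):
        pts, groups = separable(n_per=4)
        with pytest.raises(ValueError, match="positive-eigenvalue"):
            po.cap_fit(euclid_dm(pts), groups, m=20)


class TestCapLoo:
    def test_planted_mislabeled_point_is_the_error(self):
        pts, groups = separable(n_per=8)
        groups = list(groups)
        groups[3] = "peri-implantitis"  # tight healthy point, wrong label
        alloc, success = po.cap_loo(euclid_dm(pts), groups, m=2)
        wrong = alloc.index[~alloc["correct"]]
        assert list(wrong) == ["s3"]
        assert success == pytest.approx(15 / 16)

    def test_success_invariant_to_sample_order(self):
        pts, groups = separable(sep=3.0, seed=7)
        dm = euclid_dm(pts)
        _, s1 = po.cap_loo(dm, groups, m=3)
        order = np.random.default_rng(1).permutation(len(groups))
        dm2 = DistanceMatrix(dm.data[np.ix_(order, order)],
                             ids=[dm.ids[i] for i in order])
        _, s2 = po.cap_loo(dm2, [groups[i] for i in order], m=3)
        assert s1 == pytest.approx(s2)

    def test_loo_matches_model_record(self):
        pts, groups = separable(sep=2.5, seed=2)
        model = po.cap_fit(euclid_dm(pts), groups, m=3)
        alloc, success = po.cap_loo(euclid_dm(pts), groups, m=3)
        assert model.loo_success == success
        pd.testing.assert_frame_equal(model.loo_allocation, alloc)


class TestCapPredict:
    def test_training_sample_projects_onto_itself(self):
        pts, groups = separable(sep=4.0, seed=4)
        dm = euclid_dm(pts)
        model = po.cap_fit(dm, groups, m=3)
        new_d = pd.DataFrame(dm.data[[2]], index=["again"],
                             columns=list(dm.ids))
        pred = po.cap_predict(model, new_d)
        expect = model.canonical_scores.iloc[2]
        got = pred[list(model.centroids.columns)].iloc[0]
        np.testing.assert_allclose(got.to_numpy(), expect.to_numpy(), atol=1e-8)
        assert pred["predicted"].iloc[0] == model.loo_allocation["true"].iloc[2]

    def test_equidistant_tie_breaks_lexicographically(self):
        pts, groups = separable(n_per=4, sep=6.0, seed=0)
        dm = euclid_dm(pts)
        model = po.cap_fit(dm, groups, m=1)
        # construct a fake distance row projecting exactly onto the midpoint
        mid = model.centroids.to_numpy().mean(axis=0)
        # search a synthetic point along the axis: use the training points'
        # mean distances as a base and verify tie flag via equal centroids
        model.centroids.iloc[0] = model.centroids.iloc[1]
        new_d = pd.DataFrame(dm.data[[0]], index=["n"], columns=list(dm.ids))
        pred = po.cap_predict(model, new_d)
        assert pred["predicted"].iloc[0] == sorted(model.group_names)[0]
        assert bool(pred["tie"].iloc[0])

    def test_heldout_cohort_accuracy(self):
        # train and test drawn from the same two separated populations
        rng = np.random.default_rng(8)
        def draw(n_per):
            a = rng.normal(0, 1, (n_per, 4))
            b = rng.normal(0, 1, (n_per, 4)); b[:, 0] += 6.0
            return np.vstack([a, b]), ["healthy"] * n_per + ["peri-implantitis"] * n_per
        train_pts, train_groups = draw(12)
        test_pts, test_groups = draw(10)
        dm = euclid_dm(train_pts)
        model = po.cap_fit(dm, train_groups, m=3)
        new_d = pd.DataFrame(cdist(test_pts, train_pts),
                             index=[f"t{i}" for i in range(20)],
                             columns=list(dm.ids))
        pred = po.cap_predict(model, new_d)
        acc = np.mean(pred["predicted"].to_numpy() == np.array(test_groups))
        assert acc >= 0.9


class TestFeatureCorrelations:
    def test_feature_equal_to_axis_scores(self, species_block):
        logged, dm, model = species_block
        cap1 = model.canonical_scores.iloc[:, 0]
        data = logged.data.copy()
        data["planted"] = cap1 - cap1.min() + 0.001
        t = po.FeatureTable(data, scale=logged.scale)
        corr = po.cap_feature_correlations(t, model)
        assert corr.loc["planted", "r"] == pytest.approx(1.0)
        assert bool(corr.loc["planted", "candidate"])

    def test_constant_feature_flagged_zero(self, species_block):
        logged, dm, model = species_block
        data = logged.data.copy()
        data["flat"] = 0.25
        corr = po.cap_feature_correlations(
            po.FeatureTable(data, scale=logged.scale), model)
        assert corr.loc["flat", "r"] == 0.0
        assert bool(corr.loc["flat", "undefined"])

    def test_matches_rank_then_pearson_oracle(self):
        pts, groups = separable(n_per=4, sep=3.0, seed=6)
        dm = euclid_dm(pts)
        model = po.cap_fit(dm, groups, m=2)
        rng = np.random.default_rng(3)
        values = rng.random((8, 5))
        t = po.FeatureTable(pd.DataFrame(values, index=list(dm.ids),
                                         columns=list("abcde")),
                            scale="log1p-relative")
        corr = po.cap_feature_correlations(t, model)
        cap1 = model.canonical_scores.iloc[:, 0].to_numpy()
        for j, f in enumerate("abcde"):
            expect = pearsonr(rankdata(values[:, j]), rankdata(cap1)).statistic
            assert corr.loc[f, "r"] == pytest.approx(expect, abs=1e-12)


def test_model_bundle_round_trip(tmp_path, species_block):
    logged, dm, model = species_block
    save_model(model, tmp_path / "cap")
    back = load_model(tmp_path / "cap")
    np.testing.assert_allclose(back.delta_sq, model.delta_sq)
    np.testing.assert_allclose(back.axes, model.axes)
    new_d = pd.DataFrame(dm.data[[5]], index=["n"], columns=list(dm.ids))
    pd.testing.assert_frame_equal(po.cap_predict(back, new_d),
                                  po.cap_predict(model, new_d))
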