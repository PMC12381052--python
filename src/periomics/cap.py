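"""Canonical analysis of principal coordinates (CAP).

CAP performs a discriminant analysis on the first ``m`` principal
coordinate axes of a dissimilarity matrix: the Gower-centred matrix is
eigendecomposed, group-indicator variables are regressed on the ``m``
orthonormal axis scores, and the squared canonical correlations
``delta^2_k`` quantify how well group membership aligns with the
constrained axes.  The number of axes is chosen by maximising
leave-one-out (LOO) allocation success, new samples are placed into the
ordination by Gower addition of their distances to the training set, and
allocation is to the nearest group centroid in canonical space.

Sign convention: when a group named in ``orient_negative`` (default
``healthy``) is present, the first canonical axis is flipped so that this
group's centroid scores negative — features positively correlated with
CAP1 then read as disease-associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from periomics.ordination import gower_center
from periomics.tables import FeatureTable

_EIG_TOL = 1e-10


@dataclass
class CapModel:
    """A fitted CAP ordination, storing everything needed for projection."""

    sample_ids: list[str]
    groups: list[str]                   # per training sample
    group_names: list[str]              # sorted unique
    m: int
    eigenvalues: np.ndarray             # positive PCoA eigenvalues (descending)
    axes: np.ndarray                    # n x m orthonormal eigenvectors
    weights: np.ndarray                 # m x (g-1) canonical weights
    delta_sq: np.ndarray                # squared canonical correlations, descending
    centroids: pd.DataFrame             # group x canonical axes
    loo_allocation: pd.DataFrame        # sample, true, predicted, correct
    loo_success: float
    d2_row_means: np.ndarray            # training D^2 row means (Gower addition)
    d2_grand_mean: float
    m_grid_success: dict[int, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def canonical_scores(self) -> pd.DataFrame:
        scores = self.axes[:, :self.m] @ self.weights
        cols = [f"CAP{i + 1}" for i in range(scores.shape[1])]
        return pd.DataFrame(scores, index=self.sample_ids, columns=cols)


def _dummies(groups: list[str], names: list[str]) -> np.ndarray:
    y = np.zeros((len(groups), len(names)))
    for i, g in enumerate(groups):
        y[i, names.index(g)] = 1.0
    return y - y.mean(axis=0)  # centred indicators


def _pcoa_axes(d: np.ndarray):
    """Orthonormal positive-eigenvalue axes of the Gower-centred matrix."""
    g = gower_center(d)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > _EIG_TOL * max(vals.max(), 1.0)
    return vals[pos], vecs[:, pos]


def _canonical(q_m: np.ndarray, groups: list[str], names: list[str]):
    """Eigen-analysis of Q_m' H Q_m -> (delta_sq, weights)."""
    y = _dummies(groups, names)
    # H projects onto the span of the centred group indicators
    coef, *_ = np.linalg.lstsq(y, q_m, rcond=None)
    hq = y @ coef
    a = q_m.T @ hq
    a = (a + a.T) / 2
    vals, vecs = np.linalg.eigh(a)
    order = np.argsort(vals)[::-1]
    k = len(names) - 1
    delta_sq = np.clip(vals[order][:k], 0.0, 1.0)
    weights = vecs[:, order][:, :k]
    return delta_sq, weights


def _allocate(scores: np.ndarray, centroids: np.ndarray,
              names: list[str]) -> tuple[list[str], list[bool]]:
    """Nearest-centroid allocation; ties break to the lexicographically
    first group name (names are pre-sorted)."""
    preds, ties = [], []
    for s in scores:
        d = np.linalg.norm(centroids - s, axis=1)
        best = float(d.min())
        winners = np.flatnonzero(np.isclose(d, best, rtol=0, atol=1e-12))
        preds.append(names[winners[0]])
        ties.append(len(winners) > 1)
    return preds, ties


def _project(d2_new: np.ndarray, d2_row_means: np.ndarray, d2_grand: float,
             axes: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """Gower addition of new points (rows of squared distances to training).

    ``g_new,i = -1/2 (d^2_new,i - r_i - r_new + s)``; the orthonormal axis
    score on axis k is ``(q_k . g_new) / lambda_k`` so that a duplicated
    training point recovers its own axis scores exactly.
    """
    d2_new = np.atleast_2d(d2_new)
    r_new = d2_new.mean(axis=1, keepdims=True)
    g_new = -0.5 * (d2_new - d2_row_means[None, :] - r_new + d2_grand)
    return (g_new @ axes) / eigenvalues[None, :]


def _fit_at_m(d: np.ndarray, groups: list[str], names: list[str], m: int):
    vals, vecs = _pcoa_axes(d)
    if m > len(vals):
        raise ValueError(f"m={m} exceeds the {len(vals)} positive-eigenvalue axes")
    q_m = vecs[:, :m]
    delta_sq, weights = _canonical(q_m, groups, names)
    return vals, vecs, delta_sq, weights


def cap_loo(dm: DistanceMatrix, groups, m: int,
            orient_negative: str | None = "healthy") -> tuple[pd.DataFrame, float]:
    """Leave-one-out allocation success of CAP with ``m`` axes.

    Each sample in turn is held out, the model is refitted on the n-1
    remaining samples, the held-out sample is projected by Gower addition
    and allocated to the nearest group centroid in canonical space.
    """
    groups = [str(g) for g in groups]
    names = sorted(set(groups))
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    records = []
    for i in range(n):
        keep = np.arange(n) != i
        d_sub = d[np.ix_(keep, keep)]
        sub_groups = [g for j, g in enumerate(groups) if j != i]
        vals, vecs = _pcoa_axes(d_sub)
        m_i = max(min(m, len(sub_groups) - len(names), len(vals)), 1)
        q_m = vecs[:, :m_i]
        delta_sq, weights = _canonical(q_m, sub_groups, names)
        scores = q_m @ weights
        cents = np.vstack([scores[[g == nm for g in sub_groups]].mean(axis=0)
                           for nm in names])
        d2_sub = d_sub ** 2
        row_means = d2_sub.mean(axis=1)
        grand = d2_sub.mean()
        proj = _project(d[i, keep] ** 2, row_means, grand, vecs, vals)
        new_score = proj[:, :m_i] @ weights
        pred, _ = _allocate(new_score, cents, names)
        records.append({"sample_id": dm.ids[i], "true": groups[i],
                        "predicted": pred[0], "correct": pred[0] == groups[i]})
    alloc = pd.DataFrame(records).set_index("sample_id")
    return alloc, float(alloc["correct"].mean())


def cap_fit(dm: DistanceMatrix, groups, m: int | None = None,
            m_grid=None, orient_negative: str | None = "healthy",
            provenance: dict | None = None) -> CapModel:
    """Fit a CAP model on a distance matrix and group labels.

    If ``m`` is not given it is selected from ``m_grid`` (default
    ``1..min(n-g, 30)``, capped by the positive-eigenvalue count) by
    maximising LOO allocation success, ties going to the smallest ``m``.
    """
    groups = [str(g) for g in groups]
    names = sorted(set(groups))
    g_count = len(names)
    n = len(groups)
    if g_count < 2:
        raise ValueError("cap_fit needs at least 2 groups")
    if n < g_count + 2:
        raise ValueError(f"cap_fit needs n >= g+2 samples, got {n}")
    d = np.asarray(dm.data, dtype=float)

    m_grid_success: dict[int, float] = {}
    if m is None:
        vals0, _ = _pcoa_axes(d)
        hi = min(n - g_count, 30, len(vals0))
        grid = list(m_grid) if m_grid is not None else list(range(1, hi + 1))
        best_m, best_s = None, -1.0
        for mm in grid:
            if mm > len(vals0):
                continue
            _, s = cap_loo(dm, groups, mm, orient_negative)
            m_grid_success[mm] = s
            if s > best_s + 1e-12:
                best_m, best_s = mm, s
        if best_m is None:
            raise ValueError("no feasible m in the grid")
        m = best_m

    vals, vecs, delta_sq, weights = _fit_at_m(d, groups, names, m)
    q_m = vecs[:, :m]

    # orientation: the designated group's centroid scores negative on CAP1
    scores = q_m @ weights
    if orient_negative is not None and orient_negative in names:
        ref = scores[[g == orient_negative for g in groups], 0].mean()
        if ref > 0:
            weights = weights.copy()
            weights[:, 0] *= -1
            scores = q_m @ weights

    cent = np.vstack([scores[[g == nm for g in groups]].mean(axis=0) for nm in names])
    centroids = pd.DataFrame(cent, index=names,
                             columns=[f"CAP{i + 1}" for i in range(scores.shape[1])])
    alloc, success = cap_loo(dm, groups, m, orient_negative)
    d2 = d ** 2
    return CapModel(
        sample_ids=list(dm.ids), groups=groups, group_names=names, m=m,
        eigenvalues=vals, axes=vecs, weights=weights, delta_sq=delta_sq,
        centroids=centroids, loo_allocation=alloc, loo_success=success,
        d2_row_means=d2.mean(axis=1), d2_grand_mean=float(d2.mean()),
        m_grid_success=m_grid_success, provenance=provenance or {},
    )


def cap_predict(model: CapModel, new_distances: pd.DataFrame) -> pd.DataFrame:
    """Allocate new samples from their distances to the training samples.

    ``new_distances`` is new-samples x training-samples (columns in
    training order, checked by id).  New samples must have been processed
    with the training transform (same features, relative + log1p, Bray-
    Curtis against the training profiles).  Returns predicted group,
    canonical scores and a tie flag per new sample.
    """
    cols = list(new_distances.columns)
    if cols != model.sample_ids:
        try:
            new_distances = new_distances[model.sample_ids]
        except KeyError as exc:
            raise ValueError("new_distances columns must match training sample ids") from exc
    d2_new = new_distances.to_numpy(dtype=float) ** 2
    proj = _project(d2_new, model.d2_row_means, model.d2_grand_mean,
                    model.axes, model.eigenvalues)
    scores = proj[:, :model.m] @ model.weights
    preds, ties = _allocate(scores, model.centroids.to_numpy(), model.group_names)
    out = pd.DataFrame(scores, index=new_distances.index,
                       columns=list(model.centroids.columns))
    out.insert(0, "predicted", preds)
    out["tie"] = ties
    return out


def cap_feature_correlations(table: FeatureTable, model: CapModel,
                             cutoff: float = 0.4) -> pd.DataFrame:
    """Spearman rank correlation of each feature with the CAP1 scores.

    Features with |r| above ``cutoff`` are flagged as biomarker
    candidates; features constant across samples have no defined rank
    correlation and are reported as r = 0 with ``undefined = True``.
    """
    if list(table.sample_ids) != model.sample_ids:
        raise ValueError("table samples must match the fitted model")
    cap1 = model.canonical_scores.iloc[:, 0].to_numpy()
    records = []
    for fid in table.feature_ids:
        x = table.data[fid].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(cap1) == 0:
            records.append({"feature_id": fid, "r": 0.0, "undefined": True,
                            "candidate": False})
            continue
        r = float(spearmanr(x, cap1).statistic)
        records.append({"feature_id": fid, "r": r, "undefined": False,
                        "candidate": abs(r) > cutoff})
    return pd.DataFrame(records).set_index("feature_id")


# ---------------------------------------------------------------------------
# On-disk bundle (TSV matrices + JSON manifest)


def save_model(model: CapModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.axes, index=model.sample_ids).to_csv(d / "axes.tsv", sep="\t")
    pd.DataFrame(model.weights).to_csv(d / "weights.tsv", sep="\t")
    model.centroids.to_csv(d / "centroids.tsv", sep="\t")
    model.loo_allocation.to_csv(d / "loo.tsv", sep="\t")
    manifest = {
        "sample_ids": model.sample_ids, "groups": model.groups,
        "group_names": model.group_names, "m": model.m,
        "eigenvalues": model.eigenvalues.tolist(),
        "delta_sq": model.delta_sq.tolist(),
        "loo_success": model.loo_success,
        "d2_row_means": model.d2_row_means.tolist(),
        "d2_grand_mean": model.d2_grand_mean,
        "m_grid_success": {str(k): v for k, v in model.m_grid_success.items()},
        "provenance": model.provenance,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(directory) -> CapModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    axes = pd.read_csv(d / "axes.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    weights = pd.read_csv(d / "weights.tsv", sep="\t", index_col=0).to_numpy(dtype=float)
    centroids = pd.read_csv(d / "centroids.tsv", sep="\t", index_col=0)
    loo = pd.read_csv(d / "loo.tsv", sep="\t", index_col=0)
    return CapModel(
        sample_ids=manifest["sample_ids"], groups=manifest["groups"],
        group_names=manifest["group_names"], m=manifest["m"],
        eigenvalues=np.asarray(manifest["eigenvalues"]), axes=axes,
        weights=weights, delta_sq=np.asarray(manifest["delta_sq"]),
        centroids=centroids, loo_allocation=loo,
        loo_success=manifest["loo_success"],
        d2_row_means=np.asarray(manifest["d2_row_means"]),
        d2_grand_mean=manifest["d2_grand_mean"],
        m_grid_success={int(k): v for k, v in manifest["m_grid_success"].items()},
        provenance=manifest["provenance"],
    )
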