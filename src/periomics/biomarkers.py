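"""Random-forest biomarker discovery on CAP-preselected DNA/RNA features.

Feature blocks (species, genus, EC) are first reduced to the features
whose Spearman correlation with the CAP1 axis exceeds a cutoff, then
combined into named datasets (``species``, ``genus``, ``EC``,
``species+EC``, ``genus+EC``).  Each dataset is scored by a random forest
under 20-times-repeated stratified 10-fold cross-validation (mean AUC of
the pooled out-of-fold probabilities per repeat) and leave-one-out
accuracy.  Recursive feature elimination removes the 10 least important
features per iteration, scoring each subset size by cross-validation, and
the final report joins feature importances with Cohen's d and BH q-values
from the univariate screen.

Note: pre-selection on the full dataset before cross-validation mirrors
common biomarker practice but leaks selection information into the CV
estimate; ``assemble_datasets`` therefore records the cutoff used, and a
nested scheme can be emulated by calling it inside an outer loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from periomics.cap import CapModel, cap_feature_correlations
from periomics.tables import FeatureTable, SampleMetadata

DATASET_NAMES = ("species", "genus", "EC", "species+EC", "genus+EC")


@dataclass
class BiomarkerDataset:
    """A named, pre-selected samples x features matrix with labels."""

    name: str
    matrix: pd.DataFrame
    labels: pd.Series          # diagnosis per sample, aligned with matrix
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.columns.has_duplicates:
            raise ValueError(f"dataset {self.name!r}: duplicate feature ids")
        if not self.matrix.index.equals(self.labels.index):
            raise ValueError(f"dataset {self.name!r}: labels misaligned")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def assemble_datasets(blocks: dict[str, tuple[FeatureTable, CapModel]],
                      metadata: SampleMetadata,
                      r_cut: float = 0.4) -> dict[str, BiomarkerDataset]:
    """Build the five biomarker datasets from per-block tables and CAP fits.

    ``blocks`` maps block names (``species``, ``genus``, ``EC``) to the
    transformed table used for the CAP fit and the fitted model.  Within
    each block only features with ``|r| > r_cut`` against CAP1 survive;
    combination datasets concatenate the filtered blocks column-wise with
    source-prefixed feature ids.  Empty datasets are kept (downstream
    evaluation rejects them explicitly).
    """
    filtered: dict[str, pd.DataFrame] = {}
    for name, (table, model) in blocks.items():
        corr = cap_feature_correlations(table, model, cutoff=r_cut)
        keep = list(corr.index[corr["candidate"]])
        sub = table.data[keep].copy()
        sub.columns = [f"{name}:{c}" for c in sub.columns]
        filtered[name] = sub

    first = next(iter(blocks.values()))[0]
    labels = metadata.diagnosis(first.sample_ids)

    datasets: dict[str, BiomarkerDataset] = {}
    for name in DATASET_NAMES:
        parts = name.split("+")
        if not all(p in filtered for p in parts):
            continue
        matrix = pd.concat([filtered[p] for p in parts], axis=1)
        datasets[name] = BiomarkerDataset(
            name=name, matrix=matrix, labels=labels.loc[matrix.index],
            provenance={"r_cut": r_cut, "blocks": parts,
                        "n_features": int(matrix.shape[1])})
    return datasets


@dataclass
class ModelEvaluation:
    """Cross-validated performance of one biomarker dataset."""

    dataset: str
    mean_auc: float
    auc_per_repeat: np.ndarray
    loocv_accuracy: float
    importances: pd.Series                 # mean decrease in impurity
    tuned_params: dict
    rfe_profile: pd.DataFrame | None = None   # size -> cv_auc
    optimal_size: int | None = None
    optimal_features: list[str] | None = None


def _encode(labels: pd.Series) -> tuple[np.ndarray, str]:
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError(f"binary labels required, got {names}")
    positive = names[-1]  # lexicographically last = disease label
    return (labels == positive).to_numpy().astype(int), positive


def _tune(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
          n_trees: int, n_candidates: int = 10) -> dict:
    """Random grid over mtry / min leaf size, scored by inner 5-fold AUC."""
    n_feat = x.shape[1]
    best, best_score = {"max_features": "sqrt", "min_samples_leaf": 1}, -np.inf
    for _ in range(n_candidates):
        params = {
            "max_features": max(1, int(rng.integers(1, max(2, int(np.sqrt(n_feat) * 2))))),
            "min_samples_leaf": int(rng.integers(1, 6)),
        }
        skf = StratifiedKFold(n_splits=5, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        prob = np.zeros(len(y))
        for train, test in skf.split(x, y):
            clf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31)),
                **params)
            clf.fit(x[train], y[train])
            prob[test] = clf.predict_proba(x[test])[:, 1]
        score = roc_auc_score(y, prob)
        if score > best_score:
            best, best_score = params, score
    return best


def rf_evaluate(ds: BiomarkerDataset, repeats: int = 20, folds: int = 10,
                seed: int = 0, n_trees: int = 500,
                tune: bool = True, loocv: bool = True) -> ModelEvaluation:
    """Repeated stratified k-fold AUC and LOOCV accuracy of a random forest.

    Out-of-fold class probabilities are pooled within each repeat and
    scored once per repeat; the headline number is their mean.  All
    randomness (tuning, fold shuffling, forests) flows from ``seed``.
    """
    if ds.n_features == 0:
        raise ValueError(f"dataset {ds.name!r} has no features after pre-selection")
    x = ds.matrix.to_numpy(dtype=float)
    y, positive = _encode(ds.labels)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} samples, got {counts}")
    rng = np.random.default_rng(seed)
    params = _tune(x, y, rng, n_trees) if tune else {"max_features": "sqrt",
                                                     "min_samples_leaf": 1}

    aucs = np.empty(repeats)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        prob = np.zeros(len(y))
        for train, test in skf.split(x, y):
            clf = RandomForestClassifier(n_estimators=n_trees,
                                         random_state=int(rng.integers(2**31)),
                                         **params)
            clf.fit(x[train], y[train])
            prob[test] = clf.predict_proba(x[test])[:, 1]
        aucs[rep] = roc_auc_score(y, prob)

    # LOOCV accuracy with the same tuned forest
    loocv_acc = float("nan")
    if loocv:
        correct = 0
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            clf = RandomForestClassifier(n_estimators=n_trees,
                                         random_state=int(rng.integers(2**31)),
                                         **params)
            clf.fit(x[mask], y[mask])
            correct += int(clf.predict(x[~mask])[0] == y[i])
        loocv_acc = correct / len(y)

    full = RandomForestClassifier(n_estimators=n_trees,
                                  random_state=int(rng.integers(2**31)), **params)
    full.fit(x, y)
    importances = pd.Series(full.feature_importances_, index=ds.matrix.columns,
                            name="importance").sort_values(ascending=False)
    return ModelEvaluation(dataset=ds.name, mean_auc=float(aucs.mean()),
                           auc_per_repeat=aucs, loocv_accuracy=loocv_acc,
                           importances=importances,
                           tuned_params={**params, "positive_label": positive})


def rfe(ds: BiomarkerDataset, step: int = 10, folds: int = 10, seed: int = 0,
        n_trees: int = 500, min_features: int = 1) -> ModelEvaluation:
    """Recursive feature elimination with cross-validated profile.

    At each subset size the CV AUC is recorded and the ``step`` features
    with the lowest full-data importance are dropped; the optimal size
    maximises the CV metric, ties to the smaller size.
    """
    if ds.n_features == 0:
        raise ValueError(f"dataset {ds.name!r} has no features")
    y, positive = _encode(ds.labels)
    rng = np.random.default_rng(seed)
    current = list(ds.matrix.columns)
    profile_rows = []
    subsets: dict[int, list[str]] = {}
    while True:
        x = ds.matrix[current].to_numpy(dtype=float)
        n_splits = min(folds, np.bincount(y).min())
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        prob = np.zeros(len(y))
        for train, test in skf.split(x, y):
            clf = RandomForestClassifier(n_estimators=n_trees,
                                         random_state=int(rng.integers(2**31)))
            clf.fit(x[train], y[train])
            prob[test] = clf.predict_proba(x[test])[:, 1]
        auc = roc_auc_score(y, prob)
        profile_rows.append({"size": len(current), "cv_auc": float(auc)})
        subsets[len(current)] = list(current)
        if len(current) <= min_features:
            break
        full = RandomForestClassifier(n_estimators=n_trees,
                                      random_state=int(rng.integers(2**31)))
        full.fit(ds.matrix[current].to_numpy(dtype=float), y)
        order = np.argsort(full.feature_importances_, kind="stable")
        n_drop = min(step, len(current) - min_features)
        drop = {current[i] for i in order[:n_drop]}
        current = [c for c in current if c not in drop]

    profile = pd.DataFrame(profile_rows).set_index("size")
    best_auc = profile["cv_auc"].max()
    optimal = min(s for s, a in profile["cv_auc"].items()
                  if a >= best_auc - 1e-12)
    final = RandomForestClassifier(n_estimators=n_trees,
                                   random_state=int(rng.integers(2**31)))
    final.fit(ds.matrix[subsets[optimal]].to_numpy(dtype=float), y)
    importances = pd.Series(final.feature_importances_, index=subsets[optimal],
                            name="importance").sort_values(ascending=False)
    return ModelEvaluation(dataset=ds.name,
                           mean_auc=float(profile.loc[optimal, "cv_auc"]),
                           auc_per_repeat=np.array([]),
                           loocv_accuracy=float("nan"), importances=importances,
                           tuned_params={"positive_label": positive},
                           rfe_profile=profile, optimal_size=optimal,
                           optimal_features=subsets[optimal])


def biomarker_report(evaluation: ModelEvaluation,
                     diff: pd.DataFrame,
                     d_flag: float = 0.8) -> pd.DataFrame:
    """Rank biomarkers by importance, joined with effect sizes and q-values.

    ``diff`` is a differential table indexed by (unprefixed) feature id;
    features without a differential record get NA effect size and a join
    warning flag.  ``large_effect`` marks |Cohen's d| > ``d_flag``.
    """
    rows = []
    for rank, (fid, imp) in enumerate(evaluation.importances.items(), start=1):
        bare = fid.split(":", 1)[1] if ":" in fid else fid
        if bare in diff.index:
            rec = diff.loc[bare]
            d = float(rec["cohen_d"])
            rows.append({"feature_id": fid, "rank": rank, "importance": imp,
                         "cohen_d": d, "q_value": float(rec["q_value"]),
                         "direction": rec.get("direction", ""),
                         "large_effect": bool(abs(d) > d_flag),
                         "missing_diff": False})
        else:
            rows.append({"feature_id": fid, "rank": rank, "importance": imp,
                         "cohen_d": float("nan"), "q_value": float("nan"),
                         "direction": "", "large_effect": False,
                         "missing_diff": True})
    return pd.DataFrame(rows).set_index("feature_id")
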