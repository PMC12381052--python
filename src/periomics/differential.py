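"""Univariate group comparisons and volcano-style feature selection.

The routine comparison between diagnosis groups is a two-sided
Mann-Whitney U test per feature, Benjamini-Hochberg adjusted across
features, with Cohen's d as the effect size.  A feature counts as
differentially expressed when its raw p-value is at most ``p_cut``
(default 0.001) AND the magnitude of its Spearman correlation with the
first canonical (CAP1) axis exceeds ``r_cut`` (default 0.4); the sign of
that correlation assigns the feature to the health or the disease side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from periomics.cap import CapModel, cap_feature_correlations
from periomics.tables import FeatureTable, SampleMetadata

#: maximum smaller-group size at which the exact null distribution is used
EXACT_N = 8


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation null when the smaller group has at most
    :data:`EXACT_N` observations and the data are tie-free, otherwise the
    normal approximation with tie correction.  Returns ``(U, p)`` with U
    computed for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= EXACT_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohen_d(x, y) -> float:
    """Standardised mean difference with the pooled (n-1) SD.

    Returns ``inf``/``-inf``/``nan`` when the pooled SD is zero (flag
    values, never silently clipped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    pooled = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    diff = x.mean() - y.mean()
    if pooled == 0:
        return float(np.sign(diff) * np.inf) if diff != 0 else float("nan")
    return float(diff / pooled)


def differential_table(table: FeatureTable, metadata: SampleMetadata,
                       model: CapModel | None = None,
                       r_cut: float = 0.4, p_cut: float = 0.001,
                       disease: str = "peri-implantitis") -> pd.DataFrame:
    """Per-feature Mann-Whitney + BH + Cohen's d, joined with CAP1 correlations.

    ``direction`` is ``health`` for negative CAP1 correlation and the
    disease label for positive correlation (under the convention that the
    healthy centroid scores negative); without a CAP model the sign of
    Cohen's d (disease minus health) is used instead.
    """
    metadata.validate_against(table)
    diag = metadata.diagnosis(table.sample_ids)
    labels = sorted(diag.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 diagnosis groups, got {labels}")
    if disease not in labels:
        disease = labels[-1]
    health = [g for g in labels if g != disease][0]
    in_disease = (diag == disease).to_numpy()

    values = table.values
    rows = []
    for j, fid in enumerate(table.feature_ids):
        x = values[in_disease, j]
        y = values[~in_disease, j]
        u, p = mann_whitney(x, y)
        rows.append({"feature_id": fid, "u_statistic": u, "p_value": p,
                     "cohen_d": cohen_d(x, y)})
    out = pd.DataFrame(rows).set_index("feature_id")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())

    if model is not None:
        corr = cap_feature_correlations(table, model, cutoff=r_cut)
        out["cap_r"] = corr["r"]
        out["cap_r_undefined"] = corr["undefined"]
    else:
        d = out["cohen_d"].replace([np.inf, -np.inf], np.nan)
        out["cap_r"] = np.sign(d).fillna(0.0)
        out["cap_r_undefined"] = d.isna()

    out["selected"] = (out["cap_r"].abs() > r_cut) & (out["p_value"] <= p_cut)
    out["direction"] = np.where(out["cap_r"] > 0, disease, health)
    out.loc[out["cap_r"] == 0, "direction"] = "none"
    return out


def volcano_select(diff: pd.DataFrame, r_cut: float = 0.4,
                   p_cut: float = 0.001) -> dict[str, list[str]]:
    """Partition selected features by direction, re-applying the rule.

    Returns ``{direction: [feature ids]}`` for features with
    ``|cap_r| > r_cut`` and raw ``p <= p_cut``.
    """
    sel = diff[(diff["cap_r"].abs() > r_cut) & (diff["p_value"] <= p_cut)]
    out: dict[str, list[str]] = {}
    for direction, sub in sel.groupby("direction"):
        out[str(direction)] = list(sub.index)
    return out
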