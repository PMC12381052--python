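"""Distance-based group tests: PERMANOVA with restricted permutations, PERMDISP.

PERMANOVA partitions the total sum of squared dissimilarities into
between- and within-group components and assesses the pseudo-F by
permuting group labels.  When repeated samples per patient are present,
labels are permuted only within patient blocks (the exchangeable units),
which conditions the test on the within-subject design.  PERMDISP is the
multivariate Levene analogue: an ANOVA F on the distances of samples to
their own group centroid in PCoA space, with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from skbio import DistanceMatrix

from periomics.ordination import pcoa_eig


@dataclass
class PermTestResult:
    """Permutation test outcome with the scheme that produced it."""

    statistic: float          # pseudo-F
    p_value: float            # (1 + #{F_perm >= F_obs}) / (1 + n_permutations)
    n_permutations: int
    scheme: str               # "free", "within-strata", "exhaustive"
    effect_size: float | None = None   # PERMANOVA R^2


def _group_index(groups) -> tuple[np.ndarray, list]:
    labels = np.asarray(list(groups))
    uniq = sorted(set(labels.tolist()))
    idx = np.array([uniq.index(g) for g in labels])
    return idx, uniq


def _permanova_ss(d2: np.ndarray, idx: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        if len(members) < 2:
            continue
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    return ss_total - ss_within, ss_within


def _permanova_f(d2: np.ndarray, idx: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_between, ss_within = _permanova_ss(d2, idx, n_groups)
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def _strata_permutation(rng: np.random.Generator, idx: np.ndarray,
                        blocks: list[np.ndarray]) -> np.ndarray:
    out = idx.copy()
    for members in blocks:
        out[members] = idx[rng.permutation(members)]
    return out


def permanova(dm: DistanceMatrix, groups, strata=None, n_perm: int = 99_999,
              seed: int | None = 0) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    groups:
        Group label per sample, aligned with ``dm.ids``.
    strata:
        Optional block label per sample (e.g. patient id).  Group labels
        are then shuffled only within each block; blocks that carry a
        single group label contribute no permutation variability (warned).
    n_perm:
        Number of label permutations (99,999 matches routine practice for
        a definitive run; use fewer for simulation studies).
    """
    idx, uniq = _group_index(groups)
    n = dm.shape[0]
    if len(uniq) < 2:
        raise ValueError("permanova needs at least 2 groups")
    counts = np.bincount(idx, minlength=len(uniq))
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _permanova_f(d2, idx, len(uniq))

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(list(strata))
        blocks = [np.flatnonzero(strata == b) for b in sorted(set(strata.tolist()))]
        degenerate = [b for b in blocks if len(set(idx[b])) < 2]
        if degenerate:
            warnings.warn(
                f"{len(degenerate)} strata block(s) carry a single group label "
                "and contribute no permutation variability", stacklevel=2)
        scheme = "within-strata"
        draw = lambda: _strata_permutation(rng, idx, blocks)  # noqa: E731
    else:
        scheme = "free"
        draw = lambda: rng.permutation(idx)  # noqa: E731

    exceed = 0
    for _ in range(n_perm):
        exceed += _permanova_f(d2, draw(), len(uniq)) >= f_obs
    p = (1 + exceed) / (1 + n_perm)

    # R^2 = SS_between / SS_total, the standard companion statistic
    ss_between, ss_within = _permanova_ss(d2, idx, len(uniq))
    return PermTestResult(statistic=float(f_obs), p_value=float(p),
                          n_permutations=n_perm, scheme=scheme,
                          effect_size=float(ss_between / (ss_between + ss_within)))


def permanova_exhaustive(dm: DistanceMatrix, groups) -> PermTestResult:
    """Exact PERMANOVA p-value by enumerating all distinct relabelings.

    Only practical for tiny designs; the p-value is the fraction of
    relabelings (including the observed one) whose pseudo-F is >= the
    observed pseudo-F.
    """
    from itertools import combinations

    idx, uniq = _group_index(groups)
    if len(uniq) != 2:
        raise ValueError("exhaustive enumeration implemented for 2 groups")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = len(idx)
    n1 = int((idx == 0).sum())
    f_obs = _permanova_f(d2, idx, 2)
    f_all = []
    for members in combinations(range(n), n1):
        perm = np.ones(n, dtype=int)
        perm[list(members)] = 0
        f_all.append(_permanova_f(d2, perm, 2))
    f_all = np.asarray(f_all)
    p = float((f_all >= f_obs - 1e-12).mean())
    return PermTestResult(statistic=float(f_obs), p_value=p,
                          n_permutations=len(f_all) - 1, scheme="exhaustive")


def _centroid_distances(dm: DistanceMatrix, idx: np.ndarray,
                        n_groups: int) -> np.ndarray:
    """Distance of each sample to its own group centroid in PCoA space.

    Centroids live in the positive-eigenvalue principal-coordinate space;
    squared distances are clipped at zero before the square root to guard
    against small negative round-off.
    """
    vals, vecs = pcoa_eig(dm)
    pos = vals > 1e-10 * max(vals.max(), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    z = np.empty(len(idx))
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        centroid = coords[members].mean(axis=0)
        sq = ((coords[members] - centroid) ** 2).sum(axis=1)
        z[members] = np.sqrt(np.clip(sq, 0.0, None))
    return z


def _anova_f(z: np.ndarray, idx: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(idx == g)
        m = z[members].mean()
        ss_between += len(members) * (m - grand) ** 2
        ss_within += ((z[members] - m) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 999,
             seed: int | None = 0) -> PermTestResult:
    """Homogeneity of multivariate dispersions (distance-to-centroid Levene).

    The observed F compares group means of the distances to own-group
    centroids; the null distribution permutes those centroid distances
    across samples (residual permutation), keeping centroids fixed.
    """
    idx, uniq = _group_index(groups)
    if len(uniq) < 2:
        raise ValueError("permdisp needs at least 2 groups")
    counts = np.bincount(idx, minlength=len(uniq))
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    z = _centroid_distances(dm, idx, len(uniq))
    f_obs = _anova_f(z, idx, len(uniq))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += _anova_f(z[rng.permutation(len(z))], idx, len(uniq)) >= f_obs
    p = (1 + exceed) / (1 + n_perm)
    return PermTestResult(statistic=float(f_obs), p_value=float(p),
                          n_permutations=n_perm, scheme="free")
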