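"""Distance-based permutation tests for group structure: ANOSIM and PERMANOVA.

Both tests assess whether a labelled grouping explains the structure of a
dissimilarity matrix.  ANOSIM compares mean between- and within-group
ranks of the dissimilarities (R in [-1, 1]); PERMANOVA partitions
distance-based sums of squares into between and within components
(pseudo-F, with R^2 = SS_between / SS_total as effect size).  Significance
comes from permuting sample labels; the observed statistic is included in
the permutation distribution so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["PermTestResult", "anosim", "permanova"]


@dataclass
class PermTestResult:
    statistic_name: str
    statistic: float
    effect_size: float
    p_value: float
    permutations: int
    seed: int | None = None


def _prepare(d: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray]:
    from .community import validate_distance_matrix

    validate_distance_matrix(d)
    labels = np.asarray(pd.Series(groups).reindex(d.index) if isinstance(groups, pd.Series) else groups)
    if len(labels) != d.shape[0]:
        raise ValueError("group labels do not match distance matrix samples")
    if pd.isna(labels).any():
        raise ValueError("missing group label")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups with fewer than 2 members: {list(small)}")
    return d.to_numpy(dtype=float), labels


def _anosim_r(ranks: np.ndarray, same: np.ndarray, m: int) -> float:
    rw = ranks[same].mean()
    rb = ranks[~same].mean()
    return float((rb - rw) / (m / 2.0))


def _distinct_label_permutations(labels: np.ndarray, limit: int = 200_000):
    seen = set()
    for perm in iter_permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)
        if len(seen) > limit:
            raise ValueError("too many distinct permutations for exhaustive mode")


def anosim(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermTestResult:
    """Analysis of similarities (Clarke's R) with label-permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    M = n(n-1)/2 dissimilarity pairs ranked with ties averaged.  In
    ``exhaustive`` mode every distinct label permutation is enumerated and
    p is the exact fraction with R >= observed.
    """
    a, labels = _prepare(d, groups)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(a[iu])
    m = len(ranks)

    def same_mask(lab: np.ndarray) -> np.ndarray:
        return lab[iu[0]] == lab[iu[1]]

    r_obs = _anosim_r(ranks, same_mask(labels), m)

    if exhaustive:
        perm_r = np.array(
            [_anosim_r(ranks, same_mask(p), m) for p in _distinct_label_permutations(labels)]
        )
        p_value = float((perm_r >= r_obs - 1e-12).mean())
        return PermTestResult("R", r_obs, r_obs, p_value, len(perm_r), seed)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, same_mask(perm), m) >= r_obs - 1e-12:
            hits += 1
    p_value = (1 + hits) / (1 + n_perm)
    return PermTestResult("R", r_obs, r_obs, float(p_value), n_perm, seed)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray, iu) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and labels."""
    n = d2.shape[0]
    pair_d2 = d2[iu]
    ss_total = pair_d2.sum() / n
    uniq = np.unique(labels)
    ss_within = 0.0
    for g in uniq:
        idx = labels == g
        ng = int(idx.sum())
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    a_groups = len(uniq)
    f = (ss_between / (a_groups - 1)) / (ss_within / (n - a_groups))
    r2 = ss_between / ss_total
    return float(f), float(r2)


def permanova(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermTestResult:
    """One-factor permutational multivariate analysis of variance.

    SS_total = sum of squared dissimilarities / n; SS_within accumulates
    within-group pair sums scaled by group size; pseudo-F and the
    permutation p-value follow Anderson's construction.
    """
    a, labels = _prepare(d, groups)
    d2 = a**2
    iu = np.triu_indices(a.shape[0], k=1)
    f_obs, r2 = _permanova_stats(d2, labels, iu)

    if exhaustive:
        perm_f = np.array(
            [
                _permanova_stats(d2, p, iu)[0]
                for p in _distinct_label_permutations(labels)
            ]
        )
        p_value = float((perm_f >= f_obs - 1e-12).mean())
        return PermTestResult("pseudo-F", f_obs, r2, p_value, len(perm_f), seed)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_stats(d2, perm, iu)[0] >= f_obs - 1e-12:
            hits += 1
    p_value = (1 + hits) / (1 + n_perm)
    return PermTestResult("pseudo-F", f_obs, r2, float(p_value), n_perm, seed)
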