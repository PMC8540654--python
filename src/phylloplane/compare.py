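"""Site/category mean comparisons: ANOVA, corrected pairwise t-tests,
and the superscript-letter significance encoding used in the field table."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairwiseResults",
    "one_way_anova",
    "pairwise_t_tests",
    "significance_letters",
]

_CORRECTIONS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


def _split(values, groups) -> dict[str, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g):
        raise ValueError("values and groups differ in length")
    out = {lab: v[g == lab] for lab in pd.unique(g)}
    small = [lab for lab, arr in out.items() if len(arr) < 2]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    if small:
        raise ValueError(f"groups with n < 2: {small}")
    return out


def one_way_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across groups."""
    by_group = _split(values, groups)
    arrays = list(by_group.values())
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero residual variance: ANOVA undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class PairwiseResults:
    """All-pairs t-test results with multiplicity-adjusted p-values."""

    table: pd.DataFrame  # group_a, group_b, t, p_raw, p_adj
    correction: str


def pairwise_t_tests(
    values, groups, correction: str = "bh", equal_var: bool = False
) -> PairwiseResults:
    """Two-sided t-tests for every unordered group pair.

    Welch's t by default (``equal_var=True`` for pooled variance).
    ``correction`` is ``bonferroni`` (p_adj = min(1, p*m)) or ``bh``
    (Benjamini-Hochberg step-up over the m pairs).
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    by_group = _split(values, groups)
    rows = []
    for a, b in combinations(by_group, 2):
        t, p = stats.ttest_ind(by_group[a], by_group[b], equal_var=equal_var)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(table["p_raw"], method=_CORRECTIONS[correction])
    table["p_adj"] = p_adj
    return PairwiseResults(table=table, correction=correction)


def significance_letters(
    results: PairwiseResults, site_order: Sequence[str], alpha: float = 0.05
) -> dict[str, str]:
    """Superscript letters marking which sites each site differs from.

    Site i in ``site_order`` is denoted by letter ``u`` + i; a site's
    string lists the letters of every site it differs from at adjusted
    p < alpha, in fixed site order.
    """
    letters = {site: chr(ord("u") + i) for i, site in enumerate(site_order)}
    diff: dict[str, set[str]] = {site: set() for site in site_order}
    for _, row in results.table.iterrows():
        a, b = row["group_a"], row["group_b"]
        if a not in letters or b not in letters:
            raise ValueError(f"pair ({a}, {b}) outside site order")
        if row["p_adj"] < alpha:
            diff[a].add(b)
            diff[b].add(a)
    return {
        site: "".join(letters[o] for o in site_order if o in diff[site])
        for site in site_order
    }
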