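"""Indicator-taxon discovery: Kruskal-Wallis screen + LDA effect size.

Differentially abundant taxa between BC-load categories are found the way
LEfSe does it: aggregate counts to a taxonomic rank, express them per
million, keep taxa whose Kruskal-Wallis p is below alpha, then score each
candidate by a bootstrapped linear-discriminant effect size on the
per-million scale; only log10 scores >= 2 (i.e. effects of at least 100
per-million units) are reported.  The subclass (pairwise Wilcoxon) stage of
the original LEfSe is omitted because the study design defines no
subclasses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import kruskal

from .community import AsvTable

__all__ = [
    "RankAbundance",
    "IndicatorResult",
    "aggregate_to_rank",
    "kruskal_wallis_screen",
    "lda_effect_size",
    "find_indicators",
]

PER_MILLION = 1e6


@dataclass
class RankAbundance:
    """Per-million relative abundance aggregated to one taxonomic rank."""

    abundance: pd.DataFrame  # rank labels x samples
    rank: str


def aggregate_to_rank(table: AsvTable, rank: str) -> RankAbundance:
    """Sum ASV counts by rank label and convert to per-million abundance.

    Missing/empty labels at the rank are pooled under
    ``unclassified_<parent label>`` using the next-higher assigned rank, so
    no reads are dropped and sample totals are conserved.
    """
    if table.taxonomy is None:
        raise ValueError("taxonomy required for rank aggregation")
    tax = table.taxonomy
    if rank not in tax.columns:
        raise ValueError(f"rank {rank!r} not in taxonomy columns {list(tax.columns)}")
    cols = list(tax.columns)
    rank_pos = cols.index(rank)

    def label_for(taxon: str) -> str:
        row = tax.loc[taxon]
        value = row[rank]
        if pd.notna(value) and str(value).strip():
            return str(value)
        for parent in cols[:rank_pos][::-1]:
            pv = row[parent]
            if pd.notna(pv) and str(pv).strip():
                return f"unclassified_{pv}"
        return "unclassified_root"

    labels = pd.Series({t: label_for(t) for t in table.counts.index})
    summed = table.counts.groupby(labels.reindex(table.counts.index)).sum()
    totals = summed.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero sample has no relative abundance")
    rel = summed.div(totals, axis=1) * PER_MILLION
    return RankAbundance(abundance=rel, rank=rank)


def kruskal_wallis_screen(
    m: RankAbundance | pd.DataFrame, groups, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-taxon Kruskal-Wallis test across groups.

    Returns a DataFrame indexed by taxon with columns ``H``, ``p``,
    ``selected`` (p < alpha) and ``note``.  Taxa that are constant across
    all samples have an undefined test and are excluded (note
    ``constant``).
    """
    values = m.abundance if isinstance(m, RankAbundance) else m
    labels = np.asarray(groups)
    if len(labels) != values.shape[1]:
        raise ValueError("group labels do not match samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    rows = []
    for taxon, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        if np.all(x == x[0]):
            rows.append({"taxon": taxon, "H": np.nan, "p": np.nan,
                         "selected": False, "note": "constant"})
            continue
        h, p = kruskal(*[x[labels == g] for g in uniq])
        rows.append({"taxon": taxon, "H": float(h), "p": float(p),
                     "selected": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows).set_index("taxon")


@dataclass
class IndicatorResult:
    """Filtered indicator table plus the full pre-filter scores."""

    table: pd.DataFrame  # taxon, rank, category, p, lda_score (filtered)
    scores: pd.DataFrame  # all candidates, before the score threshold


def _lda_axis(x: np.ndarray, y: np.ndarray, classes: np.ndarray, ridge: float) -> np.ndarray:
    """First discriminant axis of a ridge-regularised LDA fit."""
    p = x.shape[1]
    grand = x.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for g in classes:
        xg = x[y == g]
        mu = xg.mean(axis=0)
        dev = xg - mu
        sw += dev.T @ dev
        diff = (mu - grand)[:, None]
        sb += len(xg) * (diff @ diff.T)
    # relative ridge keeps the regularisation meaningful at per-million scale
    scale = max(np.trace(sw) / p, 1.0)
    sw = sw + ridge * scale * np.eye(p)
    eigval, eigvec = linalg.eigh(sb, sw)
    w = eigvec[:, -1]
    return w / max(np.linalg.norm(w), 1e-300)


def lda_effect_size(
    m: RankAbundance | pd.DataFrame,
    groups,
    candidates,
    n_boot: int = 30,
    boot_fraction: float = 2 / 3,
    seed: int | None = None,
    score_threshold: float = 2.0,
    ridge: float = 1e-6,
    p_values: pd.Series | None = None,
) -> IndicatorResult:
    """Bootstrapped LDA effect size for screened candidate taxa.

    Per bootstrap, a stratified ``boot_fraction`` subsample is drawn per
    class and a regularised all-class LDA is fitted on the candidate
    features; a feature's raw effect is the average of (a) its largest
    absolute between-class mean difference and (b) the largest absolute
    between-class difference of its contribution along the first
    discriminant axis.  The score is log10 of the bootstrap-mean raw effect
    (floored at 1, so scores are non-negative).  Each candidate is assigned
    the class in which its full-data mean is highest; rows with score >=
    ``score_threshold`` form the indicator table.
    """
    values = m.abundance if isinstance(m, RankAbundance) else m
    rank = m.rank if isinstance(m, RankAbundance) else ""
    labels = np.asarray(groups)
    candidates = [c for c in candidates]
    empty_cols = ["rank", "category", "p", "lda_score"]
    if not candidates:
        empty = pd.DataFrame(columns=empty_cols)
        return IndicatorResult(table=empty, scores=empty.copy())

    x_full = values.loc[candidates].to_numpy(dtype=float).T  # samples x feats
    classes = np.unique(labels)
    class_idx = {g: np.where(labels == g)[0] for g in classes}
    if any(len(ix) < 3 for ix in class_idx.values()):
        raise ValueError("each class needs >= 3 samples for bootstrapped LDA")

    rng = np.random.default_rng(seed)
    n_feat = len(candidates)
    raw = np.zeros(n_feat)
    for _ in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(ix, size=max(3, int(np.ceil(boot_fraction * len(ix)))), replace=False)
                for g, ix in class_idx.items()
            ]
        )
        xb, yb = x_full[take], labels[take]
        mus = {g: xb[yb == g].mean(axis=0) for g in classes}
        mean_diff = np.max(
            [np.abs(mus[g1] - mus[g2]) for g1, g2 in combinations(classes, 2)], axis=0
        )
        w = _lda_axis(xb, yb, classes, ridge)
        proj_diff = np.max(
            [np.abs(w * mus[g1] - w * mus[g2]) for g1, g2 in combinations(classes, 2)],
            axis=0,
        )
        raw += (mean_diff + proj_diff) / 2.0
    raw /= n_boot
    score = np.log10(np.maximum(raw, 1.0))

    full_means = {g: x_full[labels == g].mean(axis=0) for g in classes}
    enriched = [classes[int(np.argmax([full_means[g][i] for g in classes]))] for i in range(n_feat)]

    scores = pd.DataFrame(
        {
            "rank": rank,
            "category": enriched,
            "p": (p_values.reindex(candidates) if p_values is not None else np.nan),
            "lda_score": score,
        },
        index=pd.Index(candidates, name="taxon"),
    )
    table = scores[scores["lda_score"] >= score_threshold].sort_values(
        "lda_score", ascending=False
    )
    return IndicatorResult(table=table, scores=scores)


def find_indicators(
    table: AsvTable,
    groups,
    rank: str = "genus",
    alpha: float = 0.05,
    score_threshold: float = 2.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> IndicatorResult:
    """Full screen-then-score chain at one taxonomic rank."""
    ra = aggregate_to_rank(table, rank)
    screen = kruskal_wallis_screen(ra, groups, alpha=alpha)
    cands = list(screen.index[screen["selected"]])
    return lda_effect_size(
        ra,
        groups,
        cands,
        seed=seed,
        n_boot=n_boot,
        score_threshold=score_threshold,
        p_values=screen["p"],
    )
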