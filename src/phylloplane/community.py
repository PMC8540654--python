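"""Count-table handling, alpha diversity, rarefaction and Bray-Curtis.

The analysis chain mirrors standard amplicon practice: drop shallow samples
(< 500 reads), discard chloroplast lineages, scale counts by
``S(x) = log10(x + 1)``, normalise every sample to an even depth of 1e6,
then measure beta diversity on Bray-Curtis dissimilarities of the
transformed profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "AbundanceMatrix",
    "filter_samples",
    "remove_taxa_by_lineage",
    "transform_counts",
    "alpha_diversity",
    "rarefaction_curves",
    "bray_curtis",
]

DEPTH_SCALE = 1e6


@dataclass
class AsvTable:
    """Integer count matrix (taxa x samples) with optional ranked taxonomy."""

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if c.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.taxonomy is not None:
            missing = c.index.difference(self.taxonomy.index)
            if len(missing):
                raise ValueError(f"taxa missing from taxonomy: {list(missing)[:5]}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_taxa(self, taxa: Sequence[str]) -> "AsvTable":
        tax = self.taxonomy.loc[taxa] if self.taxonomy is not None else None
        return AsvTable(self.counts.loc[taxa], tax)

    def subset_samples(self, samples: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts[list(samples)], self.taxonomy)


@dataclass
class AbundanceMatrix:
    """Real-valued taxa x samples matrix after a documented transform."""

    values: pd.DataFrame
    transform: str = "identity"


def filter_samples(table: AsvTable, min_reads: int = 500) -> AsvTable:
    """Drop samples whose total read count is strictly below ``min_reads``."""
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= min_reads]
    if len(keep) == 0:
        raise ValueError(f"no sample reaches {min_reads} reads")
    return table.subset_samples(keep)


def remove_taxa_by_lineage(table: AsvTable, label: str = "Chloroplast") -> AsvTable:
    """Remove taxa whose lineage contains ``label`` at any rank (case-insensitive)."""
    if table.taxonomy is None:
        raise ValueError("taxonomy required to filter by lineage")
    lineage = table.taxonomy.astype("string").fillna("")
    hit = lineage.apply(lambda col: col.str.contains(label, case=False)).any(axis=1)
    keep = table.counts.index[~hit.reindex(table.counts.index, fill_value=False)]
    return table.subset_taxa(keep)


def transform_counts(table: AsvTable) -> AbundanceMatrix:
    """log10(x+1) scaling followed by even-depth normalisation to 1e6.

    Each sample column of the result sums to exactly 1e6 (up to float
    round-off); all-zero samples are rejected since the normalisation is
    undefined for them.
    """
    x = table.counts.astype(float)
    scaled = np.log10(x + 1.0)
    colsums = scaled.sum(axis=0)
    zero = colsums.index[colsums == 0]
    if len(zero):
        raise ValueError(f"all-zero samples cannot be depth-normalised: {list(zero)[:5]}")
    normalised = scaled.div(colsums, axis=1) * DEPTH_SCALE
    return AbundanceMatrix(values=normalised, transform="log10p1+per-million")


def alpha_diversity(table: AsvTable, base: float | None = None) -> pd.DataFrame:
    """Observed taxon richness and Shannon diversity per sample.

    Shannon H = -sum p_i log p_i over within-sample proportions; natural
    log by default (pass ``base`` to change it).
    """
    x = table.counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals == 0).any():
        empty = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"empty samples have undefined diversity: {empty[:5]}")
    p = x / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0)
    if base is not None:
        h = h / np.log(base)
    return pd.DataFrame(
        {"observed": (x > 0).sum(axis=0), "shannon": h}, index=table.sample_ids
    )


def rarefaction_curves(
    table: AsvTable,
    depths: Sequence[int],
    reps: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    Reads are subsampled without replacement (multivariate hypergeometric
    draws) and richness is averaged over ``reps`` draws.  Depths exceeding
    a sample's total are skipped for that sample (NaN) with a warning.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=table.sample_ids, columns=list(depths), dtype=float)
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        for d in depths:
            if d > total:
                warnings.warn(
                    f"depth {d} exceeds total {total} for sample {sample}; skipped"
                )
                continue
            obs = [
                int((rng.multivariate_hypergeometric(col, d) > 0).sum())
                for _ in range(reps)
            ]
            out.loc[sample, d] = float(np.mean(obs))
    return out


def bray_curtis(m: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(a,b) = sum|a-b| / sum(a+b) between samples.

    Input is taxa x samples; output is a symmetric samples x samples
    DataFrame with zero diagonal and entries in [0, 1].
    """
    values = m.values if isinstance(m, AbundanceMatrix) else m
    a = values.to_numpy(dtype=float).T  # samples x taxa
    if a.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    num = np.abs(a[:, None, :] - a[None, :, :]).sum(axis=2)
    den = (a[:, None, :] + a[None, :, :]).sum(axis=2)
    both_zero = (den == 0) & ~np.eye(len(a), dtype=bool)
    if both_zero.any():
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    ids = list(values.columns)
    return pd.DataFrame(d, index=ids, columns=ids)


def validate_distance_matrix(d: pd.DataFrame, atol: float = 1e-8) -> None:
    """Raise if ``d`` is not a square symmetric zero-diagonal matrix."""
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching ids")
    if not np.allclose(a, a.T, atol=atol):
        ij = np.unravel_index(np.argmax(np.abs(a - a.T)), a.shape)
        raise ValueError(f"asymmetric distance matrix at {d.index[ij[0]]},{d.columns[ij[1]]}")
    if not np.allclose(np.diag(a), 0.0, atol=atol):
        raise ValueError("distance matrix diagonal must be zero")
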