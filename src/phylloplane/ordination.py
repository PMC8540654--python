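"""Ordination of dissimilarity matrices: metric PCoA and non-metric MDS.

PCoA eigendecomposes the Gower-centred squared-distance matrix; negative
eigenvalues (possible for semi-metrics like Bray-Curtis) are reported, not
corrected.  NMDS minimises Kruskal stress-1 by alternating isotonic
regression of configuration distances on the input dissimilarity order with
Guttman-transform updates, over several seeded restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .community import validate_distance_matrix

__all__ = ["OrdinationResult", "pcoa", "nmds"]


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    method: str
    eigenvalues: np.ndarray | None = None  # PCoA, full spectrum
    stress: float | None = None  # NMDS, Kruskal stress-1
    converged: bool = True


def pcoa(d: pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for the ``k``
    largest positive eigenvalues.  If fewer than ``k`` positive eigenvalues
    exist, the dimensionality is reduced with a warning.
    """
    validate_distance_matrix(d)
    a = d.to_numpy(dtype=float)
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (a**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0))
    n_pos = int((eigval > tol).sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; reducing k from {k}")
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.index, columns=[f"PCo{i+1}" for i in range(k)]
        ),
        method="pcoa",
        eigenvalues=eigval,
    )


def _stress_and_disparities(
    dist_config: np.ndarray, dissim: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the monotone-regressed disparities.

    ``order`` sorts condensed dissimilarities ascending; disparities are the
    isotonic fit of configuration distances in that order, rescaled to the
    configuration's sum of squares.
    """
    dhat = np.empty_like(dist_config)
    dhat[order] = isotonic_regression(dist_config[order])
    ss = (dist_config**2).sum()
    if ss <= 0:
        return 0.0, dhat
    dhat *= np.sqrt(ss / max((dhat**2).sum(), 1e-300))
    stress = np.sqrt(((dist_config - dhat) ** 2).sum() / ss)
    return float(stress), dhat


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    The first restart starts from the PCoA configuration, the rest from
    seeded random configurations; the lowest-stress solution wins.  If no
    restart reaches the stress-change tolerance within ``max_iter``
    iterations the best effort is returned with ``converged=False``.
    """
    validate_distance_matrix(d)
    n = d.shape[0]
    if n <= k:
        raise ValueError(f"need more samples ({n}) than dimensions ({k})")
    dissim = squareform(d.to_numpy(dtype=float), checks=False)
    order = np.argsort(dissim, kind="stable")
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, bool] | None = None
    for restart in range(max(1, restarts)):
        if restart == 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                start = pcoa(d, k=min(k, n - 1)).coordinates.to_numpy()
            if start.shape[1] < k:  # pad degenerate starts
                pad = rng.normal(scale=1e-4, size=(n, k - start.shape[1]))
                start = np.hstack([start, pad])
            x = start
        else:
            x = rng.normal(size=(n, k))
        prev = np.inf
        converged = False
        stress = np.inf
        for _ in range(max_iter):
            dist = pdist(x)
            stress, dhat = _stress_and_disparities(dist, dissim, order)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            bmat = -squareform(ratio)
            np.fill_diagonal(bmat, -bmat.sum(axis=1))
            x = bmat @ x / n
            x -= x.mean(axis=0)
        if best is None or stress < best[0]:
            best = (stress, x, converged)

    stress, x, converged = best
    if not converged:
        warnings.warn("NMDS did not converge in any restart; returning best effort")
    return OrdinationResult(
        coordinates=pd.DataFrame(
            x, index=d.index, columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        method="nmds",
        stress=stress,
        converged=converged,
    )
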