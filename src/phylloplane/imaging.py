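"""Black-carbon particle calling from two-channel z-stacks.

BC particles emit non-incandescence-related white light in both the narrow
second-harmonic generation (SHG) band and the broad autofluorescence (AF)
band; autofluorescent debris shows up in one channel only.  The caller
therefore thresholds each channel at 0.1% below its stack-wide intensity
maximum and counts 3D connected components of the voxelwise overlap of the
two masks.  Per-sample particle counts are converted to a per-gram leaf
load via the imaging volume and the leaf-wash suspension volume.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .simulate import ZStackPair

__all__ = [
    "ParticleSet",
    "BCLoadRecord",
    "threshold_channel",
    "coincidence_particles",
    "detect_particles",
    "bc_load",
    "category_fold_change",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # faces / +edges / +corners


def threshold_channel(channel: np.ndarray, fraction: float = 0.001) -> np.ndarray:
    """Boolean mask of voxels strictly above (1 - fraction) x the stack maximum.

    The threshold is relative to the global (3D) maximum of this channel,
    so the mask is invariant to overall intensity scaling.  An all-zero
    channel has no defined threshold and yields an empty mask with a
    warning.
    """
    if channel.size == 0:
        raise ValueError("empty channel")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    peak = float(channel.max())
    if peak <= 0:
        warnings.warn("all-zero channel: threshold undefined, returning empty mask")
        return np.zeros(channel.shape, dtype=bool)
    return channel > (1.0 - fraction) * peak


@dataclass
class ParticleSet:
    """Disjoint 3D connected components counted as BC particles."""

    count: int
    voxels: list[np.ndarray]  # per particle, (k, 3) voxel coordinates
    centroids: np.ndarray  # (count, 3)

    def __len__(self) -> int:
        return self.count


def coincidence_particles(
    mask_shg: np.ndarray, mask_af: np.ndarray, connectivity: int = 26
) -> ParticleSet:
    """Count particles as connected components of the two-channel overlap.

    Only voxels above threshold in BOTH channels survive, which rejects
    single-channel autofluorescent confounders exactly.  ``connectivity``
    is the 3D neighbourhood (6, 18 or 26).
    """
    if mask_shg.shape != mask_af.shape:
        raise ValueError(f"mask shapes differ: {mask_shg.shape} vs {mask_af.shape}")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    overlap = np.logical_and(mask_shg, mask_af)
    labels, n = measure.label(
        overlap, connectivity=_CONNECTIVITY[connectivity], return_num=True
    )
    if n == 0:
        return ParticleSet(count=0, voxels=[], centroids=np.empty((0, 3)))
    voxels = [np.argwhere(labels == i) for i in range(1, n + 1)]
    centroids = np.array(ndimage.center_of_mass(overlap, labels, range(1, n + 1)))
    return ParticleSet(count=n, voxels=voxels, centroids=centroids)


def detect_particles(
    pair: ZStackPair, fraction: float = 0.001, connectivity: int = 26
) -> ParticleSet:
    """Threshold both channels of a stack pair and count coincident particles."""
    return coincidence_particles(
        threshold_channel(pair.channel_shg, fraction),
        threshold_channel(pair.channel_af, fraction),
        connectivity=connectivity,
    )


@dataclass
class BCLoadRecord:
    """Per-sample particle counts and the derived per-gram BC load."""

    sample_id: str
    stack_counts: tuple[int, ...]
    imaging_volume_um3: float
    suspension_volume_ml: float
    leaf_mass_g: float
    load_particles_per_g: float


ML_TO_UM3 = 1e12


def bc_load(
    counts: Sequence[int],
    imaging_volume_um3: float,
    suspension_volume_ml: float,
    leaf_mass_g: float,
    sample_id: str = "",
    reducer=np.mean,
) -> BCLoadRecord:
    """Particles per gram of leaf from per-stack counts.

    The mean per-stack count is a concentration over the imaging volume;
    scaling by the total suspension volume (1 mL = 1e12 um^3) and dividing
    by the washed leaf mass gives particles per gram:

        load = mean(counts) / V_image * (V_susp * 1e12) / mass
    """
    if len(counts) == 0:
        raise ValueError("no stack counts")
    if any(c < 0 for c in counts):
        raise ValueError("negative particle count")
    if imaging_volume_um3 <= 0 or suspension_volume_ml <= 0 or leaf_mass_g <= 0:
        raise ValueError("imaging volume, suspension volume and leaf mass must be positive")
    mean_count = float(reducer(np.asarray(counts, dtype=float)))
    load = mean_count / imaging_volume_um3 * (suspension_volume_ml * ML_TO_UM3) / leaf_mass_g
    return BCLoadRecord(
        sample_id=sample_id,
        stack_counts=tuple(int(c) for c in counts),
        imaging_volume_um3=imaging_volume_um3,
        suspension_volume_ml=suspension_volume_ml,
        leaf_mass_g=leaf_mass_g,
        load_particles_per_g=load,
    )


def category_fold_change(
    site_loads: Mapping[str, float], category_map: Mapping[str, str]
) -> dict[tuple[str, str], float]:
    """Fold ratios of category mean loads for every ordered category pair.

    Category means are means of site means within the category; the ratio
    for (bcH, bcL) is mean(bcH sites) / mean(bcL sites).
    """
    cats: dict[str, list[float]] = {}
    for site, load in site_loads.items():
        if site not in category_map:
            raise ValueError(f"site {site} missing from category_map")
        cats.setdefault(category_map[site], []).append(float(load))
    means = {c: float(np.mean(v)) for c, v in cats.items()}
    out: dict[tuple[str, str], float] = {}
    for num, den in itertools.permutations(means, 2):
        if means[den] == 0:
            raise ZeroDivisionError(f"category {den} has zero mean load")
        out[(num, den)] = means[num] / means[den]
    return out
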