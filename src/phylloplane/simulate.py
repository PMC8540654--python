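"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators:

* two-channel microscope z-stacks containing coincident-emitting BC
  particles, single-channel autofluorescent confounders and background
  noise, with the planted ground truth returned alongside;
* Dirichlet-multinomial ASV count tables over the full study design, with
  a BC-load-category effect on composition that is stronger than the
  seasonal effect (the structure the field data showed), plus taxonomy and
  sample metadata;
* daily multi-pollutant time series with site-specific means and
  anti-phased NO2/O3 seasonal components.

All generators are deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import BC_CATEGORIES, SEASONS, StudyDesign, season_of_round

__all__ = [
    "ZStackPair",
    "PlantedTruth",
    "PackingError",
    "simulate_zstack_pair",
    "CommunitySimConfig",
    "CommunityTruth",
    "simulate_community",
    "simulate_pollution_series",
    "TABLE1_SITE_MEANS",
    "DEFAULT_SEASONAL_AMPLITUDES",
]

# ---------------------------------------------------------------------------
# z-stacks


@dataclass
class ZStackPair:
    """Two co-registered 3D intensity arrays, indexed (x, y, z).

    ``channel_shg`` is the narrow second-harmonic generation band and
    ``channel_af`` the broad autofluorescence band.  The default voxel size
    keeps the field study's imaging-volume aspect (lateral extent much
    larger than axial) at a downscaled lateral pixel count.
    """

    channel_shg: np.ndarray
    channel_af: np.ndarray
    voxel_size: tuple[float, float, float] = (425.1 / 64, 425.1 / 64, 1.0)

    def __post_init__(self) -> None:
        if self.channel_shg.shape != self.channel_af.shape:
            raise ValueError(
                f"channel shapes differ: {self.channel_shg.shape} vs {self.channel_af.shape}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.channel_shg.shape

    @property
    def imaging_volume_um3(self) -> float:
        return float(np.prod(self.shape) * np.prod(self.voxel_size))


@dataclass
class PlantedTruth:
    """Ground truth written by the z-stack generator."""

    particle_centers: np.ndarray  # (n, 3) int voxel coords, both channels
    confounder_centers: np.ndarray  # (m, 3) int voxel coords, AF channel only
    peak_intensity: float

    @property
    def n_particles(self) -> int:
        return len(self.particle_centers)

    @property
    def n_confounders(self) -> int:
        return len(self.confounder_centers)


class PackingError(RuntimeError):
    """Requested blobs cannot be placed without exceeding the packing limit."""


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int, int],
    margin: int,
    min_separation: int,
    existing: list[np.ndarray],
    max_tries: int = 10_000,
) -> list[np.ndarray]:
    """Rejection-sample blob centers with a Chebyshev separation floor."""
    placed: list[np.ndarray] = []
    lo = np.array([margin] * 3)
    hi = np.array(shape) - margin
    if np.any(hi <= lo):
        raise PackingError(f"shape {shape} too small for margin {margin}")
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} blobs in {shape} with separation {min_separation}"
            )
        tries += 1
        c = rng.integers(lo, hi)
        ok = all(
            np.max(np.abs(c - other)) >= min_separation for other in existing + placed
        )
        if ok:
            placed.append(c)
    return placed


def _render_blobs(
    channel: np.ndarray, centers: Sequence[np.ndarray], peak: float, sigma: float
) -> None:
    """Overlay isotropic Gaussian blobs; emission dominates background locally,
    so blob voxels replace (max), not add to, the noise."""
    if not centers:
        return
    r = max(1, int(math.ceil(4 * sigma)))
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    kernel = peak * np.exp(-(gx**2 + gy**2 + gz**2) / (2 * sigma**2))
    for c in centers:
        sl = []
        ksl = []
        for dim, cc in enumerate(c):
            lo = max(0, cc - r)
            hi = min(channel.shape[dim], cc + r + 1)
            sl.append(slice(lo, hi))
            ksl.append(slice(lo - (cc - r), hi - (cc - r)))
        region = channel[tuple(sl)]
        np.maximum(region, kernel[tuple(ksl)], out=region)


def simulate_zstack_pair(
    n_particles: int,
    n_confounders: int,
    shape: tuple[int, int, int] = (64, 64, 35),
    snr: float = 5.0,
    seed: int | None = None,
    sigma: float = 1.0,
    background_scale: float = 1.0,
    min_separation: int = 5,
) -> tuple[ZStackPair, PlantedTruth]:
    """Simulate a co-registered two-channel z-stack with planted emitters.

    Particles emit in both channels at the same voxel coordinates with peak
    intensity ``snr * background_scale``; confounders emit only in the
    autofluorescence channel.  Background noise is half-normal with scale
    ``background_scale``, truncated at 4 scale units and additionally capped
    at 0.998x the blob peak, which guarantees that no background voxel can
    clear a relative threshold of 0.1% below the stack maximum.

    Returns the stack pair and the planted ground truth.
    """
    if n_particles < 0 or n_confounders < 0:
        raise ValueError("blob counts must be non-negative")
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be three positive integers, got {shape}")
    if snr <= 1:
        raise ValueError(f"snr must exceed 1, got {snr}")
    rng = np.random.default_rng(seed)
    peak = snr * background_scale
    noise_cap = min(4.0 * background_scale, 0.998 * peak)

    def background() -> np.ndarray:
        noise = np.abs(rng.normal(0.0, background_scale, size=shape))
        return np.clip(noise, 0.0, noise_cap)

    shg = background()
    af = background()

    particles = _place_centers(rng, n_particles, shape, margin=2, min_separation=min_separation, existing=[])
    confounders = _place_centers(
        rng, n_confounders, shape, margin=2, min_separation=min_separation, existing=particles
    )

    _render_blobs(shg, particles, peak, sigma)
    _render_blobs(af, particles, peak, sigma)
    _render_blobs(af, confounders, peak, sigma)

    truth = PlantedTruth(
        particle_centers=np.array(particles, dtype=int).reshape(-1, 3),
        confounder_centers=np.array(confounders, dtype=int).reshape(-1, 3),
        peak_intensity=peak,
    )
    return ZStackPair(channel_shg=shg, channel_af=af), truth


# ---------------------------------------------------------------------------
# communities


@dataclass
class CommunitySimConfig:
    """Parameters of the Dirichlet-multinomial community generator.

    ``bc_effect_multiplier`` maps each BC-load category to the abundance
    fold-change its indicator taxa receive in samples of that category;
    season-effect taxa are boosted by ``season_effect_multiplier`` in their
    assigned peak season.  ``dispersion`` is the total Dirichlet
    concentration (larger means less compositional overdispersion).
    """

    n_taxa: int = 150
    baseline_logmean: float = 0.0
    baseline_logsd: float = 1.0
    bc_effect_taxa_fraction: float = 0.10
    bc_effect_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"bcL": 8.0, "bcM": 8.0, "bcH": 8.0}
    )
    season_effect_taxa_fraction: float = 0.10
    season_effect_multiplier: float = 2.0
    dispersion: float = 300.0
    library_size_range: tuple[int, int] = (2000, 20000)
    chloroplast_taxa: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be positive")
        for name in ("bc_effect_taxa_fraction", "season_effect_taxa_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(m <= 0 for m in self.bc_effect_multiplier.values()):
            raise ValueError("bc effect multipliers must be positive")
        if self.season_effect_multiplier <= 0:
            raise ValueError("season_effect_multiplier must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid library_size_range {self.library_size_range}")
        n_bc = round(self.bc_effect_taxa_fraction * self.n_taxa)
        n_season = round(self.season_effect_taxa_fraction * self.n_taxa)
        if n_bc + n_season > self.n_taxa:
            raise ValueError(
                f"effect taxa ({n_bc} BC + {n_season} seasonal) exceed n_taxa={self.n_taxa}"
            )


@dataclass
class CommunityTruth:
    """Which taxa carry which planted effect."""

    bc_indicator_taxa: dict[str, str]  # taxon id -> enriched BC category
    season_taxa: dict[str, str]  # taxon id -> peak season
    bc_effect_multiplier: Mapping[str, float]
    season_effect_multiplier: float


def _synthetic_lineages(taxon_ids: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Nested ranked lineages: ~2 genera per family, ~3 families per order,
    ~2 orders per class.  Each ASV gets its own genus so genus-level
    aggregation preserves planted per-taxon effects."""
    n = len(taxon_ids)
    rows = []
    for i in range(n):
        genus = f"Genus{i:04d}"
        family = f"Family{i // 2:04d}"
        order = f"Order{i // 6:04d}"
        klass = f"Class{i // 12:04d}"
        phylum = f"Phylum{i // 36:03d}"
        rows.append(
            {
                "taxon_id": taxon_ids[i],
                "kingdom": "Bacteria",
                "phylum": phylum,
                "class": klass,
                "order": order,
                "family": family,
                "genus": genus,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


def simulate_community(
    design: StudyDesign, config: CommunitySimConfig
) -> tuple["pd.DataFrame", pd.DataFrame, pd.DataFrame, CommunityTruth]:
    """Draw an ASV count table over the full study design.

    Per sample, expected relative abundances are the log-normal baseline
    re-weighted by the planted BC-category and season effects, then counts
    are drawn Dirichlet-multinomial at a library size uniform over
    ``library_size_range``.

    Returns ``(counts, taxonomy, metadata, truth)`` where ``counts`` is a
    taxa x samples integer DataFrame.
    """
    design.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_taxa
    taxon_ids = [f"ASV{i:04d}" for i in range(n)]
    baseline = rng.lognormal(config.baseline_logmean, config.baseline_logsd, size=n)

    order = rng.permutation(n)
    n_bc = round(config.bc_effect_taxa_fraction * n)
    n_season = round(config.season_effect_taxa_fraction * n)
    bc_idx = order[:n_bc]
    season_idx = order[n_bc : n_bc + n_season]

    bc_assign = {
        taxon_ids[t]: BC_CATEGORIES[j % len(BC_CATEGORIES)] for j, t in enumerate(bc_idx)
    }
    season_assign = {
        taxon_ids[t]: SEASONS[j % len(SEASONS)] for j, t in enumerate(season_idx)
    }

    sample_rows = []
    columns = {}
    lo, hi = config.library_size_range
    for site in design.sites:
        category = design.category_of(site)
        for rnd in range(1, design.rounds + 1):
            season = season_of_round(rnd)
            weights = baseline.copy()
            for j, t in enumerate(bc_idx):
                if bc_assign[taxon_ids[t]] == category:
                    weights[t] *= config.bc_effect_multiplier[category]
            for t in season_idx:
                if season_assign[taxon_ids[t]] == season:
                    weights[t] *= config.season_effect_multiplier
            p = weights / weights.sum()
            alpha = p * config.dispersion
            for pool in range(1, design.pools_per_site_round + 1):
                sample_id = f"{site}_R{rnd}_P{pool}"
                theta = rng.dirichlet(alpha)
                size = int(rng.integers(lo, hi + 1))
                columns[sample_id] = rng.multinomial(size, theta)
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "site": site,
                        "round": rnd,
                        "season": season,
                        "bc_category": category,
                        "leaf_mass_g": float(rng.lognormal(math.log(2.0), 0.15)),
                        "suspension_volume_ml": 8.0,
                    }
                )

    counts = pd.DataFrame(columns, index=pd.Index(taxon_ids, name="taxon_id"))
    taxonomy = _synthetic_lineages(taxon_ids, rng)

    if config.chloroplast_taxa > 0:
        # host-derived chloroplast reads, discarded downstream
        chl_ids = [f"CHL{i:02d}" for i in range(config.chloroplast_taxa)]
        chl_counts = rng.integers(0, 200, size=(config.chloroplast_taxa, counts.shape[1]))
        counts = pd.concat(
            [
                counts,
                pd.DataFrame(
                    chl_counts,
                    index=pd.Index(chl_ids, name="taxon_id"),
                    columns=counts.columns,
                ),
            ]
        )
        chl_tax = pd.DataFrame(
            {
                "kingdom": "Bacteria",
                "phylum": "Cyanobacteria",
                "class": "Oxyphotobacteria",
                "order": "Chloroplast",
                "family": "Chloroplast",
                "genus": "Chloroplast",
            },
            index=pd.Index(chl_ids, name="taxon_id"),
        )
        taxonomy = pd.concat([taxonomy, chl_tax])

    metadata = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = CommunityTruth(
        bc_indicator_taxa=bc_assign,
        season_taxa=season_assign,
        bc_effect_multiplier=dict(config.bc_effect_multiplier),
        season_effect_multiplier=config.season_effect_multiplier,
    )
    return counts, taxonomy, metadata, truth


# ---------------------------------------------------------------------------
# pollution series

POLLUTANTS = ("BC", "PM2.5", "PM10", "NO2", "O3")

#: Site mean concentrations (ug m^-3) of the monitored pollutants, used as
#: simulator defaults so synthetic site rankings mirror the field gradient.
TABLE1_SITE_MEANS: Mapping[str, Mapping[str, float]] = {
    "HGa": {"BC": 1.9, "PM2.5": 14.1, "PM10": 22.7, "NO2": 34.2, "O3": 42.9},
    "HGb": {"BC": 1.5, "PM2.5": 13.7, "PM10": 22.2, "NO2": 28.9, "O3": 46.9},
    "HKa": {"BC": 1.3, "PM2.5": 13.0, "PM10": 21.3, "NO2": 22.4, "O3": 49.9},
    "HKb": {"BC": 1.1, "PM2.5": 12.9, "PM10": 21.1, "NO2": 20.7, "O3": 51.0},
    "DM": {"BC": 0.9, "PM2.5": 12.1, "PM10": 19.8, "NO2": 18.5, "O3": 52.1},
    "DW": {"BC": 0.9, "PM2.5": 12.2, "PM10": 20.1, "NO2": 16.8, "O3": 53.6},
}

DEFAULT_SEASONAL_AMPLITUDES: Mapping[str, float] = {
    "BC": 0.5,
    "PM2.5": 3.0,
    "PM10": 4.0,
    "NO2": 6.0,
    "O3": 15.0,
}

# peak day-of-year per pollutant: BC and NO2 peak mid-winter, particulate
# matter late winter/early spring, O3 mid-summer (anti-phased with NO2)
_PEAK_DOY = {"BC": 15.0, "PM2.5": 60.0, "PM10": 60.0, "NO2": 15.0, "O3": 15.0 + 365.25 / 2}
_YEAR = 365.25


def simulate_pollution_series(
    site_means: Mapping[str, Mapping[str, float]] | None = None,
    seasonal_amplitudes: Mapping[str, float] | None = None,
    n_days: int = 761,
    seed: int | None = None,
    noise_fraction: float = 0.25,
    start: str = "2017-08-01",
) -> pd.DataFrame:
    """Daily pollutant series per site: seasonal sinusoid + noise, floored at 0.

    Returns a tidy DataFrame with columns ``date, site, pollutant, value``
    (ug m^-3).  NO2 and O3 seasonal components are anti-phased (winter vs
    summer peaks).
    """
    site_means = site_means if site_means is not None else TABLE1_SITE_MEANS
    seasonal_amplitudes = (
        seasonal_amplitudes if seasonal_amplitudes is not None else DEFAULT_SEASONAL_AMPLITUDES
    )
    for site, means in site_means.items():
        for pol, m in means.items():
            if m < 0:
                raise ValueError(f"negative mean for {site}/{pol}")
    if any(a < 0 for a in seasonal_amplitudes.values()):
        raise ValueError("amplitudes must be non-negative")
    if n_days < 1:
        raise ValueError("n_days must be positive")

    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    frames = []
    for site, means in site_means.items():
        for pol, mean in means.items():
            amp = seasonal_amplitudes.get(pol, 0.0)
            phase = np.cos(2 * np.pi * (doy - _PEAK_DOY.get(pol, 0.0)) / _YEAR)
            noise = rng.normal(0.0, noise_fraction * mean, size=n_days) if mean > 0 else 0.0
            values = np.clip(mean + amp * phase + noise, 0.0, None)
            frames.append(
                pd.DataFrame(
                    {"date": dates, "site": site, "pollutant": pol, "value": values}
                )
            )
    return pd.concat(frames, ignore_index=True)
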