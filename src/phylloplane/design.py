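"""Study design of the ivy-leaf field campaign.

The campaign sampled *Hedera helix* leaves at six urban/rural sites over
eight seasonal rounds (two annual cycles).  Per site and round, 80 leaves
were pooled into four metabarcoding samples and a further 10 leaves yielded
two leaf-wash aliquots for black-carbon (BC) particle imaging; each aliquot
was imaged as five z-stacks of 35 slices.  Sites fall into three phylloplane
BC-load categories (low/medium/high: bcL/bcM/bcH).

This module encodes that design and its arithmetic so that every downstream
sample count is derived, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "SEASONS",
    "DEFAULT_SITES",
    "DEFAULT_CATEGORY_MAP",
    "InvalidDesignError",
    "StudyDesign",
    "DesignSummary",
    "enumerate_design",
    "season_of_round",
]

SEASONS = ("autumn", "winter", "spring", "summer")

DEFAULT_SITES = ("HGa", "HGb", "HKa", "HKb", "DM", "DW")

#: Site -> phylloplane BC-load category (bcL/bcM/bcH).
DEFAULT_CATEGORY_MAP: Mapping[str, str] = {
    "HGa": "bcM",
    "HGb": "bcM",
    "HKa": "bcH",
    "HKb": "bcH",
    "DM": "bcL",
    "DW": "bcL",
}

BC_CATEGORIES = ("bcL", "bcM", "bcH")


class InvalidDesignError(ValueError):
    """Raised when a study design violates its invariants."""


def season_of_round(round_index: int) -> str:
    """Season of a 1-based sampling round.

    Rounds ran autumn, winter, spring, summer over two annual cycles, so
    rounds 1..8 map onto two passes through the four seasons.
    """
    if round_index < 1:
        raise ValueError(f"round_index must be >= 1, got {round_index}")
    return SEASONS[(round_index - 1) % 4]


@dataclass(frozen=True)
class StudyDesign:
    """Counts and groupings defining one sampling campaign."""

    sites: Sequence[str] = DEFAULT_SITES
    rounds: int = 8
    leaves_per_site_round_meta: int = 80
    leaves_per_site_round_bc: int = 10
    pools_per_site_round: int = 4
    bc_samples_per_site_round: int = 2
    stacks_per_sample: int = 5
    slices_per_stack: int = 35
    category_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MAP)
    )

    def validate(self) -> None:
        if len(self.sites) == 0 or len(set(self.sites)) != len(self.sites):
            raise InvalidDesignError("sites must be non-empty and unique")
        counts = {
            "rounds": self.rounds,
            "leaves_per_site_round_meta": self.leaves_per_site_round_meta,
            "leaves_per_site_round_bc": self.leaves_per_site_round_bc,
            "pools_per_site_round": self.pools_per_site_round,
            "bc_samples_per_site_round": self.bc_samples_per_site_round,
            "stacks_per_sample": self.stacks_per_sample,
            "slices_per_stack": self.slices_per_stack,
        }
        for name, value in counts.items():
            if not isinstance(value, int) or value <= 0:
                raise InvalidDesignError(f"{name} must be a positive integer, got {value!r}")
        missing = [s for s in self.sites if s not in self.category_map]
        if missing:
            raise InvalidDesignError(f"category_map missing sites: {missing}")
        bad = {s: c for s, c in self.category_map.items() if c not in BC_CATEGORIES}
        if bad:
            raise InvalidDesignError(f"unknown BC categories: {bad}")

    def category_of(self, site: str) -> str:
        return self.category_map[site]


@dataclass(frozen=True)
class DesignSummary:
    """Exact totals implied by a study design."""

    n_sites: int
    leaves_meta: int
    leaves_bc: int
    total_leaves: int
    pooled_samples: int
    bc_samples: int
    zstacks: int
    slices_per_sample: int


def enumerate_design(design: StudyDesign) -> DesignSummary:
    """Derive all sample totals from the per-site, per-round design counts.

    Every total is an exact product; e.g. the default design gives
    6 sites x 8 rounds x 80 leaves = 3840 metabarcoding leaves pooled into
    6 x 8 x 4 = 192 samples, and 5 stacks x 35 slices = 175 images per
    leaf-wash sample.
    """
    design.validate()
    n_sites = len(design.sites)
    site_rounds = n_sites * design.rounds
    leaves_meta = site_rounds * design.leaves_per_site_round_meta
    leaves_bc = site_rounds * design.leaves_per_site_round_bc
    pooled = site_rounds * design.pools_per_site_round
    bc_samples = site_rounds * design.bc_samples_per_site_round
    return DesignSummary(
        n_sites=n_sites,
        leaves_meta=leaves_meta,
        leaves_bc=leaves_bc,
        total_leaves=leaves_meta + leaves_bc,
        pooled_samples=pooled,
        bc_samples=bc_samples,
        zstacks=bc_samples * design.stacks_per_sample,
        slices_per_sample=design.stacks_per_sample * design.slices_per_stack,
    )
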