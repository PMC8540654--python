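#!/usr/bin/env python
"""Generate one full synthetic campaign: the ASV count table with taxonomy
and metadata over all 192 pooled samples, a set of two-channel z-stacks
with planted BC particles and confounders, and the daily pollution series.

Bulk data lands in scratch/campaign/ (regenerated on demand, not a
deliverable); downstream scripts read from there.
"""
from pathlib import Path

import numpy as np

from phylloplane import (
    CommunitySimConfig,
    StudyDesign,
    simulate_community,
    simulate_pollution_series,
    simulate_zstack_pair,
)
from phylloplane import io as pio
from phylloplane.community import AsvTable

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "campaign"
SEED = 20171114  # first sampling date
N_BC_SAMPLES = 8  # aliquots imaged here (2 per BC category + 2 spare)
STACKS_PER_SAMPLE = 5


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    design = StudyDesign()
    cfg = CommunitySimConfig(seed=int(rng.integers(2**31)))
    counts, taxonomy, metadata, truth = simulate_community(design, cfg)
    table = AsvTable(counts, taxonomy)
    pio.write_asv_table(table, DATA / "asv_counts.tsv", DATA / "taxonomy.tsv")
    pio.write_metadata(metadata, DATA / "metadata.tsv")
    pio.write_json(
        {"bc_indicator_taxa": truth.bc_indicator_taxa, "season_taxa": truth.season_taxa},
        DATA / "community_truth.json",
    )
    print(
        f"community: {counts.shape[0]} taxa x {counts.shape[1]} samples, "
        f"{len(truth.bc_indicator_taxa)} planted BC indicators, "
        f"{len(truth.season_taxa)} seasonal taxa"
    )

    stack_dir = DATA / "stacks"
    stack_dir.mkdir(exist_ok=True)
    for i in range(N_BC_SAMPLES):
        for j in range(STACKS_PER_SAMPLE):
            n_particles = int(rng.integers(2, 25))
            pair, truth_z = simulate_zstack_pair(
                n_particles, int(rng.integers(0, 8)), seed=int(rng.integers(2**31))
            )
            stem = f"sample{i:02d}_stack{j}"
            pio.write_zstack_pair(pair, stack_dir / f"{stem}_shg.tif", stack_dir / f"{stem}_af.tif")
            pio.write_truth(truth_z, stack_dir / f"{stem}_truth.json")
    print(f"stacks: {N_BC_SAMPLES} aliquots x {STACKS_PER_SAMPLE} z-stacks -> {stack_dir}")

    pollution = simulate_pollution_series(n_days=761, seed=int(rng.integers(2**31)))
    pollution.to_csv(DATA / "pollution_daily.tsv", sep="\t", index=False)
    print(f"pollution: {pollution['date'].nunique()} days x 6 sites x 5 pollutants")


if __name__ == "__main__":
    main()
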