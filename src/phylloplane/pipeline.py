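"""End-to-end runner: simulate -> detect -> transform -> test -> indicators.

``run_pipeline`` executes the whole chain from one seeded configuration and
writes every intermediate as text (TSV/JSON) plus a manifest of SHA-256
checksums, so a run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .community import (
    alpha_diversity,
    bray_curtis,
    filter_samples,
    remove_taxa_by_lineage,
    transform_counts,
)
from .compare import one_way_anova, pairwise_t_tests, significance_letters
from .design import StudyDesign
from .imaging import bc_load, detect_particles
from .indicators import find_indicators
from .ordination import nmds, pcoa
from .permtests import anosim, permanova
from .simulate import CommunitySimConfig, simulate_community, simulate_zstack_pair

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; YAML round-trips losslessly."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # design
    sites: tuple[str, ...] = ("HGa", "HGb", "HKa", "HKb", "DM", "DW")
    rounds: int = 8
    # community simulation
    n_taxa: int = 150
    bc_effect_multiplier: float = 8.0
    season_effect_multiplier: float = 2.0
    library_size_range: tuple[int, int] = (2000, 20000)
    # imaging simulation + detection
    n_bc_samples: int = 4
    stacks_per_sample: int = 2
    particles_per_stack: int = 10
    confounders_per_stack: int = 5
    snr: float = 5.0
    threshold_fraction: float = 0.001
    connectivity: int = 26
    # statistics
    min_reads: int = 500
    n_permutations: int = 999
    alpha: float = 0.05
    lda_threshold: float = 2.0
    indicator_rank: str = "genus"
    nmds_restarts: int = 5
    correction: str = "bh"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("sites", "library_size_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the manifest.

    The manifest records the config, per-stage outputs and their SHA-256
    checksums; identical config + seed gives identical checksums.  A stage
    failure raises :class:`PipelineError` naming the stage; outputs of
    earlier stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "files": {}}
    design = StudyDesign(sites=config.sites, rounds=config.rounds)

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = result
            return result

        return deco

    @stage("simulate_community")
    def _community():
        cfg = CommunitySimConfig(
            n_taxa=config.n_taxa,
            bc_effect_multiplier={c: config.bc_effect_multiplier for c in ("bcL", "bcM", "bcH")},
            season_effect_multiplier=config.season_effect_multiplier,
            library_size_range=config.library_size_range,
            seed=seeds[0],
        )
        counts, taxonomy, metadata, _truth = simulate_community(design, cfg)
        from .community import AsvTable

        table = AsvTable(counts=counts, taxonomy=taxonomy)
        pio.write_asv_table(table, out / "asv_counts.tsv", out / "taxonomy.tsv")
        pio.write_metadata(metadata, out / "metadata.tsv")
        return {"samples": counts.shape[1], "taxa": counts.shape[0]}

    @stage("detect_bc")
    def _detect():
        rng = np.random.default_rng(seeds[1])
        records = []
        for i in range(config.n_bc_samples):
            counts = []
            for _ in range(config.stacks_per_sample):
                pair, _truth = simulate_zstack_pair(
                    config.particles_per_stack,
                    config.confounders_per_stack,
                    snr=config.snr,
                    seed=int(rng.integers(2**31)),
                )
                counts.append(
                    detect_particles(pair, config.threshold_fraction, config.connectivity).count
                )
            records.append(
                bc_load(
                    counts,
                    imaging_volume_um3=pair.imaging_volume_um3,
                    suspension_volume_ml=8.0,
                    leaf_mass_g=2.0,
                    sample_id=f"BC{i:02d}",
                )
            )
        import pandas as pd

        df = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "stack_counts": [",".join(map(str, r.stack_counts)) for r in records],
                "load_particles_per_g": [r.load_particles_per_g for r in records],
            }
        ).set_index("sample_id")
        df.to_csv(out / "bc_loads.tsv", sep="\t")
        return {"samples": len(records), "mean_load": float(df["load_particles_per_g"].mean())}

    @stage("diversity")
    def _diversity():
        table = pio.read_asv_table(out / "asv_counts.tsv", out / "taxonomy.tsv")
        metadata = pio.read_metadata(out / "metadata.tsv")
        table = remove_taxa_by_lineage(filter_samples(table, config.min_reads))
        alpha = alpha_diversity(table)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        dist = bray_curtis(transform_counts(table))
        pio.write_distance_matrix(dist, out / "bray_curtis.tsv")
        meta = metadata.loc[dist.index]
        ords = {
            "pcoa": pcoa(dist, k=2),
            "nmds": nmds(dist, k=2, restarts=config.nmds_restarts, seed=seeds[2]),
        }
        for name, res in ords.items():
            res.coordinates.to_csv(out / f"ordination_{name}.tsv", sep="\t")
        tests = {}
        for factor in ("bc_category", "season"):
            for testname, fn in (("anosim", anosim), ("permanova", permanova)):
                r = fn(dist, meta[factor], n_perm=config.n_permutations, seed=seeds[3])
                tests[f"{testname}_{factor}"] = {
                    "statistic": r.statistic,
                    "effect_size": r.effect_size,
                    "p_value": r.p_value,
                }
        pio.write_json(tests, out / "permutation_tests.json")
        return {"samples": dist.shape[0], "nmds_stress": ords["nmds"].stress, **tests}

    @stage("indicators")
    def _indicators():
        table = pio.read_asv_table(out / "asv_counts.tsv", out / "taxonomy.tsv")
        metadata = pio.read_metadata(out / "metadata.tsv")
        table = remove_taxa_by_lineage(filter_samples(table, config.min_reads))
        meta = metadata.loc[table.sample_ids]
        res = find_indicators(
            table,
            meta["bc_category"],
            rank=config.indicator_rank,
            alpha=config.alpha,
            score_threshold=config.lda_threshold,
            seed=seeds[4],
        )
        res.table.to_csv(out / "indicators.tsv", sep="\t")
        return {"n_indicators": int(len(res.table))}

    @stage("compare")
    def _compare():
        import pandas as pd

        alpha = pd.read_csv(out / "alpha_diversity.tsv", sep="\t", index_col=0)
        metadata = pio.read_metadata(out / "metadata.tsv").loc[alpha.index]
        f, p = one_way_anova(alpha["shannon"], metadata["site"])
        pw = pairwise_t_tests(alpha["shannon"], metadata["site"], correction=config.correction)
        pw.table.to_csv(out / "pairwise_shannon.tsv", sep="\t", index=False)
        letters = significance_letters(pw, list(config.sites))
        pio.write_json({"anova_F": f, "anova_p": p, "letters": letters}, out / "site_comparison.json")
        return {"anova_F": f, "anova_p": p}

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    pio.write_json(manifest, out / "manifest.json")
    return manifest
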