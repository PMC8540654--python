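"""Readers and writers for the pipeline's on-disk formats.

Count tables, taxonomy, metadata and distance matrices are tab-separated
text; z-stacks are per-channel multi-page TIFF (one page per z slice);
ground truth and manifests are JSON.  All text is UTF-8 with '.' decimal
separators.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .community import AsvTable, validate_distance_matrix
from .simulate import PlantedTruth, ZStackPair


class SchemaError(ValueError):
    """An on-disk table violates its schema."""


# --- ASV tables -----------------------------------------------------------

def write_asv_table(table: AsvTable, counts_path, taxonomy_path=None) -> None:
    df = table.counts.copy()
    df.index.name = "taxon_id"
    df.to_csv(counts_path, sep="\t")
    if taxonomy_path is not None:
        if table.taxonomy is None:
            raise ValueError("table has no taxonomy to write")
        tx = table.taxonomy.copy()
        tx.index.name = "taxon_id"
        tx.to_csv(taxonomy_path, sep="\t")


def read_asv_table(counts_path, taxonomy_path=None) -> AsvTable:
    df = pd.read_csv(counts_path, sep="\t", index_col="taxon_id")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise SchemaError(f"non-numeric counts in {counts_path}")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise SchemaError(
            f"negative count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if not np.allclose(arr, np.round(arr)):
        raise SchemaError(f"non-integer counts in {counts_path}")
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="taxon_id")
    return AsvTable(counts=df.astype(np.int64), taxonomy=taxonomy)


# --- metadata -------------------------------------------------------------

METADATA_COLUMNS = ("site", "round", "season", "bc_category", "leaf_mass_g", "suspension_volume_ml")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    md = metadata.copy()
    md.index.name = "sample_id"
    md.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise SchemaError(f"metadata missing columns {missing}")
    if (md["leaf_mass_g"] <= 0).any():
        bad = md.index[md["leaf_mass_g"] <= 0][0]
        raise SchemaError(f"non-positive leaf mass for sample {bad!r}")
    return md


# --- distance matrices ----------------------------------------------------

def write_distance_matrix(d: pd.DataFrame, path) -> None:
    validate_distance_matrix(d)
    out = d.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", index_col="sample_id")
    d.index.name = None
    try:
        validate_distance_matrix(d)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc
    return d


# --- z-stacks -------------------------------------------------------------

def write_zstack_pair(pair: ZStackPair, shg_path, af_path) -> None:
    """One multi-page TIFF per channel, pages along z (arrays are x,y,z)."""
    for arr, path in ((pair.channel_shg, shg_path), (pair.channel_af, af_path)):
        tifffile.imwrite(path, np.moveaxis(arr, 2, 0).astype(np.float32))


def read_zstack_pair(shg_path, af_path, voxel_size=(425.1 / 64, 425.1 / 64, 1.0)) -> ZStackPair:
    shg = np.moveaxis(tifffile.imread(shg_path), 0, 2)
    af = np.moveaxis(tifffile.imread(af_path), 0, 2)
    return ZStackPair(channel_shg=shg.astype(np.float64), channel_af=af.astype(np.float64), voxel_size=voxel_size)


# --- ground truth / JSON --------------------------------------------------

def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "particle_centers": truth.particle_centers.tolist(),
        "confounder_centers": truth.confounder_centers.tolist(),
        "peak_intensity": truth.peak_intensity,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        particle_centers=np.array(payload["particle_centers"], dtype=int).reshape(-1, 3),
        confounder_centers=np.array(payload["confounder_centers"], dtype=int).reshape(-1, 3),
        peak_intensity=float(payload["peak_intensity"]),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
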