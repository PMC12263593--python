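"""Plain-text readers and writers for the package's on-disk formats.

All tabular artifacts are tab-separated with a header row:

* regional time series — first column ``region_id``, remaining columns
  ``t0, t1, ...`` timepoints;
* connectome vectors — ``edge_index, region_i, region_j, value`` in the
  canonical edge order;
* subject metadata — ``subject_id, age, sex``;
* feature sets — ``edge_index, region_i, region_j, score`` plus a JSON
  provenance sidecar;
* atlases — a voxel table ``x_voxel, y_voxel, z_voxel, region_id`` with a
  JSON affine sidecar (a NIfTI label volume can be read instead when
  nibabel is available); centroids are emitted as
  ``region_id, x_mm, y_mm, z_mm``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fc import (
    AtlasDefinition,
    ConnectomeVector,
    RegionalTimeSeries,
    edge_endpoints,
    n_edges,
)
from .leverage import FeatureSet, LeverageResult

__all__ = [
    "write_timeseries_tsv", "read_timeseries_tsv",
    "write_connectome_tsv", "read_connectome_tsv",
    "write_metadata_tsv", "read_metadata_tsv",
    "write_feature_set", "read_feature_set",
    "write_atlas_tsv", "read_atlas_tsv", "read_atlas_nifti",
    "write_centroids_tsv",
]


def write_timeseries_tsv(ts: RegionalTimeSeries, path) -> None:
    df = pd.DataFrame(ts.values, columns=[f"t{i}" for i in range(ts.n_timepoints)])
    df.insert(0, "region_id", list(ts.region_ids))
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path, subject_id: str = "", task: str = "") -> RegionalTimeSeries:
    df = pd.read_csv(path, sep="\t")
    region_ids = df["region_id"].tolist()
    values = df.drop(columns=["region_id"]).to_numpy(dtype=float)
    return RegionalTimeSeries(values=values, region_ids=region_ids, subject_id=subject_id, task=task)


def write_connectome_tsv(vec: ConnectomeVector, path) -> None:
    pairs = edge_endpoints(np.arange(len(vec)), vec.r)
    df = pd.DataFrame(
        {
            "edge_index": np.arange(len(vec)),
            "region_i": pairs[:, 0],
            "region_j": pairs[:, 1],
            "value": vec.values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_connectome_tsv(path, r: int, subject_id: str = "", task: str = "") -> ConnectomeVector:
    df = pd.read_csv(path, sep="\t")
    if len(df) != n_edges(r):
        raise ValueError(f"expected {n_edges(r)} edges for r={r}, found {len(df)}")
    values = df.sort_values("edge_index")["value"].to_numpy(dtype=float)
    return ConnectomeVector(values=values, r=r, subject_id=subject_id, task=task)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return df


def write_feature_set(
    fs: FeatureSet, r: int, path, scores: Optional[LeverageResult] = None
) -> None:
    """Feature set as TSV plus a ``<path>.json`` provenance sidecar."""
    path = Path(path)
    pairs = edge_endpoints(fs.indices, r)
    score_col = (
        scores.scores[fs.indices] if scores is not None else np.full(fs.k, np.nan)
    )
    df = pd.DataFrame(
        {
            "edge_index": fs.indices,
            "region_i": pairs[:, 0],
            "region_j": pairs[:, 1],
            "score": score_col,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "provenance": fs.provenance,
        "k": fs.k,
        "m": fs.m,
        "params": {key: _jsonable(value) for key, value in fs.params.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_set(path, m: int) -> FeatureSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    provenance, params = "leverage", {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        provenance = meta.get("provenance", provenance)
        params = meta.get("params", {})
    return FeatureSet(
        indices=df["edge_index"].to_numpy(dtype=int), m=m, provenance=provenance, params=params
    )


def write_atlas_tsv(atlas: AtlasDefinition, voxel_path, affine_path) -> None:
    rows = [(*vox, region) for vox, region in sorted(atlas.labels.items())]
    df = pd.DataFrame(rows, columns=["x_voxel", "y_voxel", "z_voxel", "region_id"])
    df.to_csv(voxel_path, sep="\t", index=False)
    Path(affine_path).write_text(
        json.dumps({"affine": atlas.affine.tolist(), "name": atlas.name}, indent=2)
    )


def read_atlas_tsv(voxel_path, affine_path) -> AtlasDefinition:
    df = pd.read_csv(voxel_path, sep="\t")
    labels = {
        (int(row.x_voxel), int(row.y_voxel), int(row.z_voxel)): int(row.region_id)
        for row in df.itertuples()
    }
    meta = json.loads(Path(affine_path).read_text())
    return AtlasDefinition(labels=labels, affine=np.asarray(meta["affine"]), name=meta.get("name", ""))


def read_atlas_nifti(path, name: str = "") -> AtlasDefinition:
    """Read an integer label volume (0 = background) as an atlas.

    Requires nibabel; kept optional because all bundled workflows run on
    text-format toy atlases.
    """
    import nibabel as nib  # optional dependency

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(int)
    labels = {
        tuple(int(c) for c in vox): int(data[tuple(vox)])
        for vox in np.argwhere(data != 0)
    }
    return AtlasDefinition(labels=labels, affine=np.asarray(img.affine), name=name or Path(path).stem)


def write_centroids_tsv(atlas: AtlasDefinition, path) -> None:
    rows = [(region, *mm) for region, mm in sorted(atlas.centroids.items())]
    df = pd.DataFrame(rows, columns=["region_id", "x_mm", "y_mm", "z_mm"])
    df.to_csv(path, sep="\t", index=False)


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value
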