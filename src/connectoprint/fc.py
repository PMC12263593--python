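"""Functional-connectome construction.

Turns regional fMRI time series into vectorized functional connectomes
(FCs) and stacks them into population matrices.  A connectome here is the
r x r matrix of pairwise Pearson correlations between regional time
series; because it is symmetric with unit diagonal, only its strict upper
triangle carries information and is stored as a length r(r-1)/2 vector of
edge features.

Edge order convention
---------------------
Edges are enumerated row-major over pairs (i, j) with i < j and 0-based
region indices: (0,1), (0,2), ..., (0,r-1), (1,2), ...  The closed form

    index(i, j) = i*r - i*(i+1)//2 + (j - i - 1)

is the inverse of :func:`edge_index_to_region_pair`.  Every feature set
produced by this package refers to this single ordering, which is what
makes feature-set intersections across cohorts, tasks and runs meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalTimeSeries",
    "ConnectomeVector",
    "PopulationMatrix",
    "AtlasDefinition",
    "n_edges",
    "edge_index_to_region_pair",
    "region_pair_to_index",
    "parcellate",
    "compute_fc",
    "vectorize_upper",
    "assemble_population",
    "exclude_low_coverage_rois",
    "edge_subset_for_regions",
    "restrict_to_regions",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RegionalTimeSeries:
    """One scan's regions x timepoints signal matrix.

    ``values`` has shape (r, t); row order follows ``region_ids``.
    """

    values: np.ndarray
    region_ids: Sequence[int]
    subject_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x timepoints matrix")
        r, t = self.values.shape
        if r < 2 or t < 2:
            raise ValueError(f"need at least 2 regions and 2 timepoints, got {r} x {t}")
        if len(self.region_ids) != r:
            raise ValueError("region_ids length must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing or non-finite values")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectomeVector:
    """Upper-triangle vectorization of one scan's correlation matrix."""

    values: np.ndarray
    r: int
    subject_id: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = n_edges(self.r)
        if self.values.shape != (expected,):
            raise ValueError(
                f"connectome vector for r={self.r} must have length {expected}, "
                f"got shape {self.values.shape}"
            )
        if self.values.size and (self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("correlation values must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PopulationMatrix:
    """Features x subjects matrix for one task.

    Column j is the connectome vector of ``subject_ids[j]``; the row
    (feature) dimension follows the canonical edge order for ``r`` regions.
    """

    values: np.ndarray
    subject_ids: Sequence[str]
    task: str
    r: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("population matrix must be 2-D (features x subjects)")
        m, n = self.values.shape
        if m != n_edges(self.r):
            raise ValueError(
                f"feature count {m} does not equal r(r-1)/2 = {n_edges(self.r)} for r={self.r}"
            )
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match the number of columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids in population matrix")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def columns_for(self, subject_ids: Sequence[str]) -> "PopulationMatrix":
        """Extract a sub-population (e.g. one age cohort), preserving order."""
        lookup = {s: j for j, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in lookup]
        if missing:
            raise KeyError(f"subjects not in population matrix: {missing[:5]}")
        cols = [lookup[s] for s in subject_ids]
        return PopulationMatrix(
            values=self.values[:, cols],
            subject_ids=list(subject_ids),
            task=self.task,
            r=self.r,
        )


@dataclass
class AtlasDefinition:
    """Region labels on a voxel grid plus region centroids in mm.

    ``labels`` maps 0-based integer voxel coordinates (i, j, k) to a region
    id; ``affine`` is the 4x4 voxel-to-mm transform; ``centroids`` maps each
    region id to the affine-transformed mean of its voxel coordinates.
    """

    labels: Mapping[tuple, int]
    affine: np.ndarray
    centroids: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if not self.centroids:
            self.centroids = self._compute_centroids()
        label_regions = set(self.labels.values())
        if set(self.centroids) != label_regions:
            raise ValueError("centroid region ids must match label region ids")

    def _compute_centroids(self) -> dict:
        by_region: dict = {}
        for vox, region in self.labels.items():
            by_region.setdefault(region, []).append(vox)
        out = {}
        for region, voxels in by_region.items():
            mean_vox = np.mean(np.asarray(voxels, dtype=float), axis=0)
            out[region] = tuple(self.voxel_to_mm(mean_vox))
        return out

    def voxel_to_mm(self, voxel) -> np.ndarray:
        v = np.append(np.asarray(voxel, dtype=float), 1.0)
        return (self.affine @ v)[:3]

    def mm_to_voxel(self, mm) -> np.ndarray:
        v = np.append(np.asarray(mm, dtype=float), 1.0)
        return (np.linalg.inv(self.affine) @ v)[:3]

    @property
    def region_ids(self) -> list:
        return sorted(set(self.labels.values()))


# ---------------------------------------------------------------------------
# edge indexing
# ---------------------------------------------------------------------------

def n_edges(r: int) -> int:
    """Number of edge features for an r-region parcellation: r(r-1)/2."""
    if r < 2:
        raise ValueError("need at least 2 regions")
    return r * (r - 1) // 2


def region_pair_to_index(i: int, j: int, r: int) -> int:
    """Canonical edge index of region pair (i, j), i < j, 0-based."""
    if not (0 <= i < j < r):
        raise ValueError(f"require 0 <= i < j < r, got i={i}, j={j}, r={r}")
    return i * r - i * (i + 1) // 2 + (j - i - 1)


def edge_index_to_region_pair(k: int, r: int) -> tuple:
    """Invert the canonical edge order: edge index -> (i, j) with i < j."""
    m = n_edges(r)
    if not (0 <= k < m):
        raise ValueError(f"edge index {k} out of range [0, {m}) for r={r}")
    # Solve for the row i such that offset(i) <= k < offset(i+1), where
    # offset(i) = i*r - i*(i+1)/2.  Quadratic inversion, then clamp for
    # floating-point safety.
    i = int((2 * r - 1 - math.sqrt((2 * r - 1) ** 2 - 8 * k)) // 2)
    while i * r - i * (i + 1) // 2 > k:
        i -= 1
    while (i + 1) * r - (i + 1) * (i + 2) // 2 <= k:
        i += 1
    j = k - (i * r - i * (i + 1) // 2) + i + 1
    return i, j


def edge_endpoints(indices, r: int) -> np.ndarray:
    """Vectorized edge index -> (i, j) lookup; returns an (n, 2) array."""
    rows, cols = np.triu_indices(r, k=1)
    idx = np.asarray(indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= rows.size):
        raise ValueError("edge index out of range")
    return np.column_stack([rows[idx], cols[idx]])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def parcellate(
    voxel_ts: np.ndarray,
    labels: Mapping[int, int],
    subject_id: str = "",
    task: str = "",
) -> RegionalTimeSeries:
    """Average voxel time series within regions.

    Parameters
    ----------
    voxel_ts : array, shape (v, t)
        Voxel-wise time series; rows are voxels.
    labels : mapping voxel row index -> region id
        Every key must index a row of ``voxel_ts``.

    Returns
    -------
    RegionalTimeSeries with one row per region (ascending region id), each
    row the arithmetic mean of that region's voxel rows per timepoint.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    if voxel_ts.ndim != 2:
        raise ValueError("voxel_ts must be 2-D (voxels x timepoints)")
    v = voxel_ts.shape[0]
    by_region: dict = {}
    for voxel, region in labels.items():
        if not (0 <= voxel < v):
            raise ValueError(f"voxel index {voxel} outside time-series rows [0, {v})")
        by_region.setdefault(region, []).append(voxel)
    region_ids = sorted(by_region)
    if not region_ids:
        raise ValueError("no regions in label mapping")
    for region in region_ids:
        if len(by_region[region]) == 0:  # defensive; unreachable via the dict
            raise ValueError(f"region {region} has zero voxels")
    rows = [voxel_ts[by_region[region]].mean(axis=0) for region in region_ids]
    return RegionalTimeSeries(
        values=np.vstack(rows), region_ids=region_ids, subject_id=subject_id, task=task
    )


def compute_fc(ts: RegionalTimeSeries) -> np.ndarray:
    """Pearson correlation matrix of the regional time series.

    Zero-variance regions cannot be correlated; their rows/columns are set
    to 0 (diagonal stays 1) and a warning is logged, so downstream leverage
    computation never sees missing values.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to correlate")
    x = ts.values
    sd = x.std(axis=1)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        logger.warning(
            "zero-variance regions %s: correlations set to 0",
            [ts.region_ids[i] for i in degenerate],
        )
        x = x.copy()
        # give flat rows unit variance noise-free placeholders, then zero out
        x[degenerate] = 0.0
        x[degenerate, 0] = 1.0
        x[degenerate, 1] = -1.0
    corr = np.corrcoef(x)
    if degenerate.size:
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def vectorize_upper(
    corr: np.ndarray, subject_id: str = "", task: str = "", tol: float = 1e-8
) -> ConnectomeVector:
    """Extract the strict upper triangle of a correlation matrix.

    The matrix must be symmetric and unit-diagonal within ``tol``.  The
    resulting vector follows the canonical edge order (see module docs).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    r = corr.shape[0]
    if r < 2:
        raise ValueError("need at least 2 regions")
    asym = np.abs(corr - corr.T).max()
    if asym > tol:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}")
    diag_err = np.abs(np.diag(corr) - 1.0).max()
    if diag_err > tol:
        raise ValueError(f"diagonal deviates from 1 by {diag_err:.3g} (tol {tol:.3g})")
    iu = np.triu_indices(r, k=1)
    return ConnectomeVector(values=corr[iu], r=r, subject_id=subject_id, task=task)


def unvectorize(vec: ConnectomeVector) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    r = vec.r
    out = np.eye(r)
    iu = np.triu_indices(r, k=1)
    out[iu] = vec.values
    out.T[iu] = vec.values
    return out


def assemble_population(
    vectors: Sequence[ConnectomeVector], subject_order: Sequence[str]
) -> PopulationMatrix:
    """Stack connectome vectors into a features x subjects matrix.

    All vectors must share ``r`` and ``task``; exactly one vector per listed
    subject, and columns follow ``subject_order``.
    """
    if not vectors:
        raise ValueError("no connectome vectors supplied")
    r = vectors[0].r
    task = vectors[0].task
    by_subject = {}
    for vec in vectors:
        if vec.r != r:
            raise ValueError(f"mixed region counts: {vec.r} != {r}")
        if vec.task != task:
            raise ValueError(f"mixed tasks: {vec.task!r} != {task!r}")
        if vec.subject_id in by_subject:
            raise ValueError(f"duplicate subject {vec.subject_id!r}")
        by_subject[vec.subject_id] = vec
    missing = [s for s in subject_order if s not in by_subject]
    if missing:
        raise ValueError(f"no connectome vector for subjects: {missing[:5]}")
    values = np.column_stack([by_subject[s].values for s in subject_order])
    return PopulationMatrix(values=values, subject_ids=list(subject_order), task=task, r=r)


def exclude_low_coverage_rois(
    mean_images: np.ndarray,
    labels: Mapping[int, int],
    mask_fraction: float = 0.7,
    coverage_min: float = 0.5,
) -> tuple:
    """ROI-coverage exclusion from per-subject mean signal-intensity images.

    A subject's functional mask is the set of voxels with intensity strictly
    above ``mask_fraction`` times that subject's mean intensity over all
    voxels.  A region's coverage for a subject is the fraction of its voxels
    inside the mask; a region is excluded iff its coverage falls strictly
    below ``coverage_min`` for at least one subject (boundary coverage is
    retained).

    Parameters
    ----------
    mean_images : array, shape (subjects, voxels)
        Non-negative mean signal intensity per voxel per subject.
    labels : mapping voxel index -> region id.

    Returns
    -------
    (retained, excluded) : sorted lists of region ids partitioning all regions.
    """
    mean_images = np.asarray(mean_images, dtype=float)
    if mean_images.ndim != 2:
        raise ValueError("mean_images must be 2-D (subjects x voxels)")
    if np.any(mean_images < 0):
        raise ValueError("intensities must be non-negative")
    v = mean_images.shape[1]
    labeled = sorted(labels)
    if labeled != list(range(v)):
        raise ValueError("every voxel must be labeled exactly once")
    by_region: dict = {}
    for voxel, region in labels.items():
        by_region.setdefault(region, []).append(voxel)
    for region, voxels in by_region.items():
        if not voxels:
            raise ValueError(f"region {region} is empty")
    thresholds = mask_fraction * mean_images.mean(axis=1, keepdims=True)
    masks = mean_images > thresholds  # (subjects, voxels)
    excluded = []
    for region in sorted(by_region):
        coverage = masks[:, by_region[region]].mean(axis=1)  # per subject
        if np.any(coverage < coverage_min):
            excluded.append(region)
    retained = [region for region in sorted(by_region) if region not in set(excluded)]
    return retained, excluded


def edge_subset_for_regions(retained_regions: Sequence[int], r: int) -> np.ndarray:
    """Edge indices (canonical order, region count r) whose both endpoints
    lie in ``retained_regions``.  Used to drop all edges touching excluded
    regions while keeping a reproducible re-indexing map."""
    keep = np.zeros(r, dtype=bool)
    keep[np.asarray(list(retained_regions), dtype=int)] = True
    rows, cols = np.triu_indices(r, k=1)
    return np.flatnonzero(keep[rows] & keep[cols])


def restrict_to_regions(M: PopulationMatrix, retained_regions: Sequence[int]) -> PopulationMatrix:
    """Population matrix restricted to the sub-parcellation ``retained_regions``.

    Rows are re-indexed to the canonical edge order of the reduced region
    set (r' = len(retained_regions)); region identity is positional in the
    retained list.
    """
    retained = sorted(retained_regions)
    kept_edges = edge_subset_for_regions(retained, M.r)
    return PopulationMatrix(
        values=M.values[kept_edges, :],
        subject_ids=list(M.subject_ids),
        task=M.task,
        r=len(retained),
    )
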