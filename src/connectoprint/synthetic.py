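"""Synthetic multi-task, multi-subject connectome studies with known truth.

The generator emulates the structure the downstream analyses assume: every
subject carries an individual-specific *fingerprint* on a planted subset of
edges that is constant across tasks; a second, disjoint subset of edges
drifts linearly with age; each task has its own group-level mean shift; and
every scan adds i.i.d. noise.  Edge values are generated directly in
correlation space and squashed through tanh so they respect [-1, 1] --
the analyses consume vectorized FCs, so full time-series synthesis is only
needed to exercise the construction stage and is provided separately by
:func:`generate_timeseries_from_fc`.

The generative model for subject s with age a_s, task tau, edge e is

    x = mu(e) + delta_tau(e) + f(s, e) * 1[e in signature]
          + beta * (a_s - midpoint) * 1[e in drift] + eps(s, tau, e)
    value = tanh(x)

with mu ~ N(0, group_mean_sd^2), delta_tau ~ N(0, task_effect_sd^2),
f ~ N(0, fingerprint_sd^2), eps ~ N(0, noise_sd^2) and beta = drift_slope
(per year).  Ages are drawn uniformly on the configured range and assigned
to subjects in sorted order, so age-cohort partitioning is deterministic;
sexes alternate M/F so both strata are always non-empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .fc import AtlasDefinition, ConnectomeVector, RegionalTimeSeries, n_edges

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_timeseries_from_fc",
    "make_toy_atlas_pair",
]

DEFAULT_TASKS = ("rest", "smt", "movie")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic connectome study.

    Defaults describe the standard study conditions used throughout the
    test-bench: 100 subjects, 60 regions (1,770 edges), 80 planted
    fingerprint edges with between-subject SD 0.5, 40 age-drift edges at
    0.01 correlation units per year, scan noise SD 0.1, ages 18-87 and the
    three task conditions rest / sensorimotor / movie watching.
    """

    n_subjects: int = 100
    n_regions: int = 60
    tasks: Tuple[str, ...] = DEFAULT_TASKS
    age_range: Tuple[float, float] = (18.0, 87.0)
    n_signature_edges: int = 80
    n_drift_edges: int = 40
    fingerprint_sd: float = 0.5
    noise_sd: float = 0.1
    drift_slope: float = 0.01
    task_effect_sd: float = 0.2
    group_mean_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("invalid config: n_subjects must be >= 1")
        if self.n_regions < 2:
            raise ValueError("invalid config: n_regions must be >= 2")
        if not self.tasks:
            raise ValueError("invalid config: at least one task required")
        if len(set(self.tasks)) != len(self.tasks):
            raise ValueError("invalid config: duplicate task labels")
        m = n_edges(self.n_regions)
        if self.n_signature_edges < 0 or self.n_drift_edges < 0:
            raise ValueError("invalid config: planted edge counts must be >= 0")
        if self.n_signature_edges + self.n_drift_edges > m:
            raise ValueError(
                "invalid config: n_signature_edges + n_drift_edges exceeds "
                f"r(r-1)/2 = {m}"
            )
        for name in ("fingerprint_sd", "noise_sd", "task_effect_sd", "group_mean_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("invalid config: age_range min must be < max")

    @property
    def m(self) -> int:
        return n_edges(self.n_regions)


@dataclass
class SyntheticStudy:
    """A generated study: metadata, connectomes, and the planted truth."""

    metadata: pd.DataFrame  # columns: subject_id, age, sex
    connectomes: Dict[Tuple[str, str], ConnectomeVector]  # (subject, task) -> vector
    truth: Dict[str, np.ndarray]  # signature_edges, drift_edges
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def subject_ids(self) -> list:
        return list(self.metadata["subject_id"])

    @property
    def ages(self) -> np.ndarray:
        return self.metadata["age"].to_numpy(dtype=float)

    def population_matrix(self, task: str):
        from .fc import assemble_population

        vectors = [self.connectomes[(s, task)] for s in self.subject_ids]
        return assemble_population(vectors, self.subject_ids)


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a synthetic study under the additive fingerprint/drift model.

    Identical config (including seed) reproduces the study bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.m
    lo, hi = config.age_range

    width = max(3, len(str(n)))
    subject_ids = [f"sub{j:0{width}d}" for j in range(1, n + 1)]
    ages = np.sort(rng.uniform(lo, hi, size=n))
    sexes = ["M" if j % 2 == 0 else "F" for j in range(n)]
    metadata = pd.DataFrame({"subject_id": subject_ids, "age": ages, "sex": sexes})

    planted = rng.choice(m, size=config.n_signature_edges + config.n_drift_edges, replace=False)
    signature = np.sort(planted[: config.n_signature_edges])
    drift = np.sort(planted[config.n_signature_edges:])

    group_mean = rng.normal(0.0, config.group_mean_sd, size=m)
    task_effect = {
        task: rng.normal(0.0, config.task_effect_sd, size=m) for task in config.tasks
    }
    fingerprint = rng.normal(0.0, config.fingerprint_sd, size=(n, signature.size))
    midpoint = 0.5 * (lo + hi)

    connectomes: Dict[Tuple[str, str], ConnectomeVector] = {}
    for j, sid in enumerate(subject_ids):
        base = group_mean.copy()
        base[signature] += fingerprint[j]
        base[drift] += config.drift_slope * (ages[j] - midpoint)
        for task in config.tasks:
            x = base + task_effect[task] + rng.normal(0.0, config.noise_sd, size=m)
            connectomes[(sid, task)] = ConnectomeVector(
                values=np.tanh(x), r=config.n_regions, subject_id=sid, task=task
            )

    truth = {"signature_edges": signature, "drift_edges": drift}
    return SyntheticStudy(metadata=metadata, connectomes=connectomes, truth=truth, config=config)


def nearest_correlation(target: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the diagonal renormalized
    to 1.  Deterministic and adequate at toy scale; not Higham's alternating
    projections.
    """
    w, v = np.linalg.eigh(target)
    w = np.clip(w, eig_floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def generate_timeseries_from_fc(
    target_corr: np.ndarray,
    t: int,
    seed: int,
    subject_id: str = "",
    task: str = "",
) -> RegionalTimeSeries:
    """Draw an r x t Gaussian time-series matrix with a given population
    correlation.

    The target is first repaired to the nearest valid correlation matrix
    (eigenvalue clipping then diagonal renormalization); sampling uses the
    eigendecomposition square root of the repaired matrix.
    """
    target_corr = np.asarray(target_corr, dtype=float)
    if target_corr.ndim != 2 or target_corr.shape[0] != target_corr.shape[1]:
        raise ValueError("target correlation must be square")
    if np.abs(target_corr - target_corr.T).max() > 1e-8:
        raise ValueError("target correlation must be symmetric")
    if np.abs(np.diag(target_corr) - 1.0).max() > 1e-8:
        raise ValueError("target correlation must have unit diagonal")
    if t < 2:
        raise ValueError("need at least t=2 timepoints")
    r = target_corr.shape[0]
    repaired = nearest_correlation(target_corr)
    w, v = np.linalg.eigh(repaired)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    values = root @ rng.standard_normal((r, t))
    return RegionalTimeSeries(
        values=values, region_ids=list(range(r)), subject_id=subject_id, task=task
    )


def _voronoi_atlas(
    grid_shape: Sequence[int], n_regions: int, seed: int, name: str, voxel_size_mm: float
) -> AtlasDefinition:
    grid_shape = tuple(int(g) for g in grid_shape)
    n_voxels = int(np.prod(grid_shape))
    if n_regions > n_voxels:
        raise ValueError(
            f"region count {n_regions} exceeds voxel count {n_voxels}"
        )
    if n_regions < 1:
        raise ValueError("need at least one region")
    rng = np.random.default_rng(seed)
    centers_flat = rng.choice(n_voxels, size=n_regions, replace=False)
    centers = np.column_stack(np.unravel_index(centers_flat, grid_shape)).astype(float)
    coords = np.column_stack(
        [g.ravel() for g in np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")]
    ).astype(float)
    # nearest center, ties broken by lowest region id (argmin is first minimum)
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignment = np.argmin(d2, axis=1)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    labels = {
        tuple(int(c) for c in coords[idx]): int(assignment[idx]) for idx in range(n_voxels)
    }
    return AtlasDefinition(labels=labels, affine=affine, name=name)


def make_toy_atlas_pair(
    grid_shape: Sequence[int] = (10, 10, 10),
    n_regions_a: int = 8,
    n_regions_b: int = 4,
    seed: int = 0,
    voxel_size_mm: float = 2.0,
) -> Tuple[AtlasDefinition, AtlasDefinition]:
    """Two complete Voronoi-style parcellations of the same voxel grid.

    Each atlas assigns every voxel to its nearest seeded center voxel;
    centroids are computed in mm through a diagonal ``voxel_size_mm``
    affine.  With equal region counts and the same seed the two atlases are
    identical by construction.
    """
    atlas_a = _voronoi_atlas(grid_shape, n_regions_a, seed, "toy_a", voxel_size_mm)
    atlas_b = _voronoi_atlas(grid_shape, n_regions_b, seed, "toy_b", voxel_size_mm)
    return atlas_a, atlas_b
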