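"""Cross-atlas concordance of frequently selected regions.

Feature selection happens independently in each parcellation, so agreement
between atlases has to be assessed in physical (mm) space.  The pipeline
is: tally how often each region appears as an endpoint of a selected edge
across cohorts; keep roughly the top half of frequently hit regions; match
region sets across atlases by looking up each region's centroid in the
other atlas's label volume; and summarize agreement with the
min-normalized overlap coefficient

    overlap(A, B) = |A ∩ B| / min(|A|, |B|),

a variant of the Dice coefficient that is robust to very different region
sizes between fine- and coarse-grained parcellations.  Centroid-in-region
lookup is a declared implementation choice: it is the simplest
deterministic operationalization of "intersecting the coordinates" of two
region sets, and it is asymmetric, so both directions can be computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, Set

import numpy as np

from .fc import AtlasDefinition, edge_endpoints
from .leverage import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "RegionFrequency",
    "region_frequencies",
    "top_frequent_regions",
    "match_regions_across_atlases",
    "overlap_coefficient",
    "voxel_overlap_percentage",
]


@dataclass
class RegionFrequency:
    """Region id -> endpoint count accumulated over cohort feature sets."""

    counts: dict
    atlas_name: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def region_frequencies(
    feature_sets: Sequence[FeatureSet],
    r: int,
    atlas_name: str = "",
    task: str = "",
    unique_per_cohort: bool = False,
) -> RegionFrequency:
    """Tally endpoint regions of selected edges over cohorts.

    By default both endpoints of every selected edge count once per cohort
    set (total = 2 * sum of set sizes); with ``unique_per_cohort`` each
    region counts at most once per cohort regardless of how many of its
    edges were selected.
    """
    counts: dict = {}
    for fs in feature_sets:
        if len(fs) == 0:
            continue
        endpoints = edge_endpoints(fs.indices, r)
        regions = endpoints.ravel()
        if unique_per_cohort:
            regions = np.unique(regions)
        for region in regions:
            counts[int(region)] = counts.get(int(region), 0) + 1
    return RegionFrequency(counts=counts, atlas_name=atlas_name, task=task)


def top_frequent_regions(freq: RegionFrequency, fraction: float = 0.5) -> Set[int]:
    """Roughly the top ``fraction`` of regions by selection frequency.

    Regions with nonzero count are ranked by (count descending, id
    ascending) and truncated to ceil(fraction * n_nonzero).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    nonzero = [(region, count) for region, count in freq.counts.items() if count > 0]
    if not nonzero:
        raise ValueError("empty region frequency: no regions were ever selected")
    nonzero.sort(key=lambda rc: (-rc[1], rc[0]))
    n_keep = math.ceil(fraction * len(nonzero))
    return {region for region, _ in nonzero[:n_keep]}


def match_regions_across_atlases(
    regions_a: Set[int],
    atlas_a: AtlasDefinition,
    regions_b: Set[int],
    atlas_b: AtlasDefinition,
) -> Set[int]:
    """Subset of ``regions_a`` whose centroids fall inside ``regions_b``.

    A region of atlas A matches iff atlas B's label at the voxel nearest to
    A's centroid (in B's voxel grid) belongs to ``regions_b``.  Centroids
    landing outside B's labeled grid are unmatched and logged.
    """
    matched = set()
    for region in regions_a:
        if region not in atlas_a.centroids:
            raise KeyError(f"region {region} has no centroid in atlas {atlas_a.name!r}")
        mm = atlas_a.centroids[region]
        voxel = tuple(int(round(c)) for c in atlas_b.mm_to_voxel(mm))
        label = atlas_b.labels.get(voxel)
        if label is None:
            logger.warning(
                "centroid of region %s (%s) falls outside atlas %s grid at voxel %s",
                region, atlas_a.name, atlas_b.name, voxel,
            )
            continue
        if label in regions_b:
            matched.add(region)
    return matched


def overlap_coefficient(set_a: Set[int], set_b: Set[int], matches: Set[int]) -> float:
    """Min-normalized overlap: |matches| / min(|A|, |B|), in [0, 1]."""
    if not set_a or not set_b:
        raise ValueError("overlap coefficient undefined for empty region sets")
    value = len(matches) / min(len(set_a), len(set_b))
    if value > 1.0:
        # many-to-one centroid matching can hit more regions than the
        # smaller set holds; the coefficient saturates at 1
        logger.info("match count %d exceeds smaller set size; coefficient capped at 1", len(matches))
    return min(value, 1.0)


def voxel_overlap_percentage(atlas_a: AtlasDefinition, atlas_b: AtlasDefinition) -> float:
    """Percent of atlas A's labeled voxels also labeled in atlas B.

    Both atlases must live on the same voxel grid (identical affines);
    resampling across grids is out of scope and raises.
    """
    if not np.allclose(atlas_a.affine, atlas_b.affine):
        raise ValueError("atlases are on different grids and no resampling rule is defined")
    voxels_a = set(atlas_a.labels)
    if not voxels_a:
        raise ValueError("atlas A labels no voxels")
    shared = voxels_a & set(atlas_b.labels)
    return 100.0 * len(shared) / len(voxels_a)
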