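"""Age-cohort partitioning and feature-set stability across cohorts.

Subjects are sorted by age and cut into non-overlapping blocks (cohorts)
of fixed size, the default 50 giving roughly 5-8 years of age span per
cohort on a lifespan sample.  Leverage-score selection is run per cohort
(and per task), and stability is measured by the pairwise percentage
intersection of the cohorts' top-k feature sets: a c x c symmetric matrix
with 100 on the diagonal.  Features present in *every* cohort's set form
the consensus — the candidate age-resilient signature.

Sex-stratified variants reuse the same machinery on metadata filtered to
one stratum; there is no separate code path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

from .fc import PopulationMatrix, edge_endpoints
from .leverage import FeatureSet, leverage_scores, select_top_k

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "IntersectionMatrix",
    "partition_cohorts",
    "per_cohort_selection",
    "intersection_matrix",
    "mean_offdiagonal",
    "consensus_features",
    "consensus_regions",
]


@dataclass
class Cohort:
    label: str
    subject_ids: List[str]
    age_min: float
    age_max: float
    stratum: str = "all"

    def __len__(self) -> int:
        return len(self.subject_ids)


@dataclass
class IntersectionMatrix:
    """Pairwise percentage intersection of cohort feature sets."""

    values: np.ndarray
    cohort_labels: List[str]
    task: str
    k: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        c = len(self.cohort_labels)
        if self.values.shape != (c, c):
            raise ValueError("intersection matrix shape must match cohort count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("intersection matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be 100 (self-intersection)")
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise ValueError("entries must lie in [0, 100]")

    @property
    def c(self) -> int:
        return len(self.cohort_labels)


def partition_cohorts(
    metadata: pd.DataFrame,
    cohort_size: int = 50,
    remainder_policy: str = "drop",
    stratum: str = "all",
) -> List[Cohort]:
    """Sort subjects by (age, subject_id) and cut consecutive blocks.

    ``remainder_policy`` controls subjects beyond the last full block:
    ``drop`` (default) leaves them unassigned, ``merge_last`` folds them
    into the final cohort.  ``stratum`` in {"all", "M", "F"} filters on the
    metadata ``sex`` column before partitioning.
    """
    if cohort_size < 2:
        raise ValueError("cohort_size must be >= 2")
    if remainder_policy not in ("drop", "merge_last"):
        raise ValueError("remainder_policy must be 'drop' or 'merge_last'")
    df = metadata
    if stratum != "all":
        if "sex" not in df.columns:
            raise ValueError("metadata lacks a sex column for stratified partitioning")
        df = df[df["sex"] == stratum]
    if df["age"].isna().any():
        raise ValueError("all subjects must have an age")
    df = df.sort_values(["age", "subject_id"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    if n < cohort_size:
        raise ValueError(f"fewer subjects ({n}) than one cohort ({cohort_size})")
    n_cohorts = n // cohort_size
    cohorts: List[Cohort] = []
    for c in range(n_cohorts):
        start = c * cohort_size
        stop = start + cohort_size
        if remainder_policy == "merge_last" and c == n_cohorts - 1:
            stop = n
        block = df.iloc[start:stop]
        cohorts.append(
            Cohort(
                label=f"cohort{c + 1:02d}",
                subject_ids=list(block["subject_id"]),
                age_min=float(block["age"].min()),
                age_max=float(block["age"].max()),
                stratum=stratum,
            )
        )
    return cohorts


def per_cohort_selection(
    M_full: PopulationMatrix,
    cohorts: Sequence[Cohort],
    k: int,
    rank_tolerance: float = 1e-10,
) -> List[FeatureSet]:
    """Top-k leverage selection on each cohort's column block of M_full."""
    out = []
    for cohort in cohorts:
        if len(cohort) < 2:
            raise ValueError(f"cohort {cohort.label} has fewer than 2 subjects")
        M_c = M_full.columns_for(cohort.subject_ids)
        result = leverage_scores(M_c, rank_tolerance=rank_tolerance, cohort=cohort.label)
        out.append(select_top_k(result, k))
    return out


def intersection_matrix(
    feature_sets: Sequence[FeatureSet],
    cohort_labels: Sequence[str] = None,
    task: str = "",
) -> IntersectionMatrix:
    """Entry (a, b) = 100 * |A intersect B| / k.

    All sets must share k: the percentages presuppose a common set size
    (min-normalized overlap is a different statistic, used only for
    cross-atlas region comparison).
    """
    if not feature_sets:
        raise ValueError("no feature sets supplied")
    ks = {fs.k for fs in feature_sets}
    if len(ks) != 1:
        raise ValueError(f"feature sets have unequal sizes {sorted(ks)}; intersection percentages require common k")
    k = ks.pop()
    if k == 0:
        raise ValueError("feature sets are empty")
    c = len(feature_sets)
    if cohort_labels is None:
        cohort_labels = [f"set{j + 1:02d}" for j in range(c)]
    sets = [fs.as_set() for fs in feature_sets]
    values = np.full((c, c), 100.0)
    for a in range(c):
        for b in range(a + 1, c):
            pct = 100.0 * len(sets[a] & sets[b]) / k
            values[a, b] = values[b, a] = pct
    return IntersectionMatrix(values=values, cohort_labels=list(cohort_labels), task=task, k=k)


def mean_offdiagonal(matrix: IntersectionMatrix, scope: str = "all_pairs") -> float:
    """Average off-diagonal intersection.

    ``consecutive`` averages the superdiagonal only (adjacent age groups);
    ``all_pairs`` averages the strict upper triangle.
    """
    c = matrix.c
    if c < 2:
        raise ValueError("need at least 2 cohorts")
    if scope == "consecutive":
        vals = np.array([matrix.values[i, i + 1] for i in range(c - 1)])
    elif scope == "all_pairs":
        iu = np.triu_indices(c, k=1)
        vals = matrix.values[iu]
    else:
        raise ValueError("scope must be 'consecutive' or 'all_pairs'")
    return float(vals.mean())


def consensus_features(feature_sets: Sequence[FeatureSet]) -> FeatureSet:
    """Features common to every cohort's set; may legitimately be empty."""
    if len(feature_sets) < 2:
        raise ValueError("consensus requires at least 2 feature sets")
    m = feature_sets[0].m
    common = feature_sets[0].as_set()
    for fs in feature_sets[1:]:
        if fs.m != m:
            raise ValueError("feature sets index different pools")
        common &= fs.as_set()
    if not common:
        logger.warning("consensus feature set is empty")
    return FeatureSet(
        indices=np.array(sorted(common), dtype=int),
        m=m,
        provenance="consensus",
        params={"n_sets": len(feature_sets)},
    )


def consensus_regions(consensus: FeatureSet, r: int) -> dict:
    """Multiset of endpoint regions of the consensus edges.

    Returns region id -> count of appearances as an edge endpoint.  Mapping
    region ids to anatomical names is a caller-side join against a lookup
    table.
    """
    counts: dict = {}
    if len(consensus) == 0:
        return counts
    endpoints = edge_endpoints(consensus.indices, r)
    for region in endpoints.ravel():
        counts[int(region)] = counts.get(int(region), 0) + 1
    return counts
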