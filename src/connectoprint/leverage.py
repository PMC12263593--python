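"""Leverage-score feature selection on population matrices.

For a tall features x subjects matrix M, let U be an orthonormal basis of
the column space of M (here: the left singular vectors for singular values
above a relative rank tolerance).  The leverage score of feature i is the
squared Euclidean norm of row i of U,

    l_i = || U_{i,.} ||^2 ,

which equals the i-th diagonal entry of the orthogonal projector
M (M^T M)^+ M^T onto the column space.  Scores lie in [0, 1] and sum to
the numerical rank; they measure how much an individual edge feature
shapes the population's subspace, i.e. how individual-specific it is.

Selection is deterministic: scores are sorted descending and the top k
features retained, with ties broken by ascending edge index so feature
sets reproduce bit-for-bit across platforms.  Randomized leverage-score
sampling is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fc import PopulationMatrix

__all__ = ["LeverageResult", "FeatureSet", "leverage_scores", "select_top_k", "sample_random_features"]


@dataclass
class LeverageResult:
    """Leverage scores of one population matrix."""

    scores: np.ndarray
    rank: int
    task: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be a vector")
        if self.scores.size and (self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9):
            raise ValueError("leverage scores must lie in [0, 1]")
        if abs(self.scores.sum() - self.rank) > 1e-6:
            raise ValueError(
                f"score sum {self.scores.sum():.8f} does not equal rank {self.rank}"
            )

    @property
    def m(self) -> int:
        return self.scores.size


@dataclass
class FeatureSet:
    """A set of edge indices with its provenance.

    ``provenance`` is one of {"leverage", "random", "consensus"}; the
    ``params`` dict records how the set was generated (task, cohort, seed).
    """

    indices: np.ndarray
    m: int
    provenance: str = "leverage"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        if self.indices.size and (self.indices.min() < 0 or self.indices.max() >= self.m):
            raise ValueError(f"feature indices must lie in [0, {self.m})")

    @property
    def k(self) -> int:
        return self.indices.size

    def __len__(self) -> int:
        return self.indices.size

    def as_set(self) -> set:
        return set(self.indices.tolist())


def leverage_scores(
    M: PopulationMatrix, rank_tolerance: float = 1e-10, cohort: str = ""
) -> LeverageResult:
    """Row leverage scores of a features x subjects matrix via thin SVD.

    Singular values below ``rank_tolerance`` times the largest are treated
    as zero, so duplicated subjects or tasks cannot inflate the basis.  The
    result is invariant (up to the tolerance) to right-multiplication of M
    by any invertible matrix, since only the column space enters.
    """
    values = M.values
    m, n = values.shape
    if m < n:
        raise ValueError(f"population matrix must be tall (m >= n), got {m} x {n}")
    norm = np.linalg.norm(values)
    if norm == 0.0:
        raise ValueError("all-zero population matrix has no column space")
    u, s, _ = np.linalg.svd(values, full_matrices=False)
    keep = s > rank_tolerance * s[0]
    rank = int(keep.sum())
    scores = np.einsum("ij,ij->i", u[:, keep], u[:, keep])
    scores = np.clip(scores, 0.0, 1.0)
    return LeverageResult(scores=scores, rank=rank, task=M.task, cohort=cohort)


def select_top_k(result: LeverageResult, k: int) -> FeatureSet:
    """Deterministically retain the k features with largest leverage scores.

    Ties are broken by ascending edge index (stable sort on descending
    score, then index).
    """
    m = result.m
    if not (1 <= k <= m):
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    order = np.lexsort((np.arange(m), -result.scores))
    chosen = np.sort(order[:k])
    return FeatureSet(
        indices=chosen,
        m=m,
        provenance="leverage",
        params={"task": result.task, "cohort": result.cohort, "k": k},
    )


def sample_random_features(
    m: int, k: int, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> FeatureSet:
    """Uniform random feature subset of size k without replacement.

    Either ``seed`` or an existing ``rng`` may be supplied; the latter lets
    callers draw many matched subsets from one seeded stream.
    """
    if k > m:
        raise ValueError(f"cannot sample {k} features from a pool of {m}")
    if rng is None:
        rng = np.random.default_rng(seed)
    indices = rng.choice(m, size=k, replace=False)
    return FeatureSet(indices=indices, m=m, provenance="random", params={"seed": seed, "k": k})
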