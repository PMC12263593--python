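"""Inter- and within-subject similarity on feature-restricted connectomes.

Two complementary views quantify how individual-specific a feature set is:

* inter-subject, within-task — Pearson correlation between every unordered
  pair of subjects' feature-restricted vectors for one task.  A good
  signature makes distinct people look *dissimilar*, so low is good.
* within-subject, cross-task — per-subject Pearson correlation between the
  same subject's vectors from two different tasks.  A good signature is
  stable across cognitive state, so high is good.

Significance is calibrated against size-matched uniform random feature
subsets: the null distribution of the same mean-similarity statistic over
many random draws, summarized by an empirical p-value with the add-one
rule (floored at 1/(n_trials+1)) and a Gaussian tail approximation that
can resolve beyond the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .fc import PopulationMatrix
from .leverage import FeatureSet, sample_random_features

logger = logging.getLogger(__name__)

__all__ = [
    "SimilaritySummary",
    "NullDistribution",
    "inter_subject_similarity",
    "within_subject_similarity",
    "random_feature_null",
]


@dataclass
class SimilaritySummary:
    mean: float
    sd: float
    n_pairs: int
    mode: str  # inter_subject_within_task | within_subject_cross_task
    task: str
    feature_provenance: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.mean <= 1.0 + 1e-9:
            raise ValueError("mean similarity must lie in [-1, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class NullDistribution:
    trial_means: np.ndarray
    n_trials: int
    seed: int
    observed: float
    side: str
    empirical_p: float
    z_p: float

    @property
    def null_mean(self) -> float:
        return float(self.trial_means.mean())

    @property
    def null_sd(self) -> float:
        return float(self.trial_means.std(ddof=1))


def _restricted(M: PopulationMatrix, features: FeatureSet) -> np.ndarray:
    if features.m != M.m:
        raise ValueError(
            f"feature set indexes a pool of {features.m} features but matrix has {M.m}"
        )
    return M.values[features.indices, :]


def _column_correlations(x: np.ndarray) -> tuple:
    """Pairwise Pearson correlations between columns of a k x n matrix.

    Returns (upper-triangle correlations over valid columns, number of
    skipped pairs).  Columns with zero variance over the k features are
    skipped.
    """
    valid = np.ptp(x, axis=0) > 0
    n = x.shape[1]
    n_total = n * (n - 1) // 2
    if valid.sum() < 2:
        raise ValueError("fewer than two subjects with non-degenerate restricted vectors")
    xv = x[:, valid]
    corr = np.corrcoef(xv.T)
    iu = np.triu_indices(valid.sum(), k=1)
    vals = corr[iu]
    n_skipped = n_total - vals.size
    if n_skipped:
        logger.warning("skipped %d subject pairs with zero-variance restricted vectors", n_skipped)
    return vals, n_skipped


def inter_subject_similarity(M: PopulationMatrix, features: FeatureSet) -> SimilaritySummary:
    """Mean/SD Pearson correlation over all unordered subject pairs within
    one task, computed on the feature-restricted vectors.

    SD is the sample standard deviation over pairs (ddof=1).
    """
    if len(features) < 3:
        raise ValueError("need at least 3 features to correlate meaningfully")
    if M.n < 2:
        raise ValueError("need at least 2 subjects")
    x = _restricted(M, features)
    vals, _ = _column_correlations(x)
    return SimilaritySummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_pairs=int(vals.size),
        mode="inter_subject_within_task",
        task=M.task,
        feature_provenance=features.provenance,
    )


def within_subject_similarity(
    M_a: PopulationMatrix, M_b: PopulationMatrix, features: FeatureSet
) -> SimilaritySummary:
    """Mean/SD per-subject Pearson correlation between two tasks' vectors.

    Both matrices must list subjects in the same order.  By convention the
    feature set is the one selected from the rest-task matrix; any set can
    be passed.
    """
    if list(M_a.subject_ids) != list(M_b.subject_ids):
        raise ValueError("subject order mismatch between the two task matrices")
    if len(features) < 3:
        raise ValueError("need at least 3 features to correlate meaningfully")
    xa = _restricted(M_a, features)
    xb = _restricted(M_b, features)
    sda = xa.std(axis=0)
    sdb = xb.std(axis=0)
    valid = (np.ptp(xa, axis=0) > 0) & (np.ptp(xb, axis=0) > 0)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("skipped %d subjects with zero-variance restricted vectors", n_skipped)
    if valid.sum() == 0:
        raise ValueError("all subjects skipped: zero-variance restricted vectors")
    za = (xa[:, valid] - xa[:, valid].mean(axis=0)) / sda[valid]
    zb = (xb[:, valid] - xb[:, valid].mean(axis=0)) / sdb[valid]
    vals = (za * zb).mean(axis=0)
    return SimilaritySummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_pairs=int(vals.size),
        mode="within_subject_cross_task",
        task=f"{M_a.task}-{M_b.task}",
        feature_provenance=features.provenance,
    )


def random_feature_null(
    M: PopulationMatrix,
    k: int,
    n_trials: int,
    seed: int,
    observed: float,
    side: str = "lower",
    M_b: Optional[PopulationMatrix] = None,
) -> NullDistribution:
    """Null distribution of mean similarity under random feature subsets.

    Each trial draws a uniform size-k subset and recomputes the mean
    similarity statistic: inter-subject within-task on ``M`` alone, or
    within-subject cross-task when ``M_b`` is given.  The empirical p-value
    uses the add-one rule, (1 + #{trials at least as extreme}) / (n_trials
    + 1), and is therefore floored at 1/(n_trials+1); ``z_p`` is the
    Gaussian tail probability under the null mean/SD, reported alongside
    because the empirical p cannot resolve below its floor.
    """
    if n_trials < 100:
        raise ValueError("need at least 100 null trials")
    if k > M.m:
        raise ValueError(f"k={k} exceeds feature pool m={M.m}")
    if side not in ("lower", "higher"):
        raise ValueError("side must be 'lower' or 'higher'")
    rng = np.random.default_rng(seed)
    trial_means = np.empty(n_trials)
    for t in range(n_trials):
        feats = sample_random_features(M.m, k, rng=rng)
        if M_b is None:
            summary = inter_subject_similarity(M, feats)
        else:
            summary = within_subject_similarity(M, M_b, feats)
        trial_means[t] = summary.mean
    if side == "lower":
        n_extreme = int((trial_means <= observed).sum())
    else:
        n_extreme = int((trial_means >= observed).sum())
    empirical_p = (1 + n_extreme) / (n_trials + 1)
    mu, sd = trial_means.mean(), trial_means.std(ddof=1)
    if sd == 0:
        z_p = 1.0 if ((side == "lower" and observed >= mu) or (side == "higher" and observed <= mu)) else 0.0
    else:
        z = (observed - mu) / sd
        z_p = float(stats.norm.cdf(z)) if side == "lower" else float(stats.norm.sf(z))
    return NullDistribution(
        trial_means=trial_means,
        n_trials=n_trials,
        seed=seed,
        observed=observed,
        side=side,
        empirical_p=empirical_p,
        z_p=z_p,
    )
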