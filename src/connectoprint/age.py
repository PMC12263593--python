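"""Age-invariance validation of stable feature sets.

Two complementary checks establish that a candidate age-resilient
signature really is age-resilient:

1. Per-feature association: each edge feature is regressed on age by
   ordinary least squares (with intercept) and the slope tested with a
   two-sided t-test; p-values are adjusted by the Benjamini-Hochberg
   step-up at a stringent level (default alpha = 0.001).  An age-resilient
   set should leave almost all features non-significant.

2. Predictive contrast: a linear model predicting chronological age from
   the feature-restricted connectome is evaluated by k-fold
   cross-validated mean absolute error (MAE, years).  Age-resilient
   features should predict age *poorly* compared with size-matched random
   feature sets, which by chance include age-drifting edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .fc import PopulationMatrix
from .leverage import FeatureSet, sample_random_features

logger = logging.getLogger(__name__)

__all__ = [
    "AgeRegressionReport",
    "CvMaeReport",
    "per_feature_age_regression",
    "fdr_adjust",
    "cv_age_prediction",
    "random_set_mae_distribution",
]


@dataclass
class AgeRegressionReport:
    """Per-feature OLS-on-age slopes and p-values, optionally FDR-flagged."""

    slopes: np.ndarray  # correlation units per year
    p_values: np.ndarray
    alpha: Optional[float] = None
    significant: Optional[np.ndarray] = None  # after FDR adjustment

    @property
    def n_features(self) -> int:
        return self.slopes.size

    @property
    def n_nonsignificant(self) -> int:
        if self.significant is None:
            raise ValueError("no FDR adjustment applied yet")
        return int((~self.significant).sum())

    def with_fdr(self, alpha: float = 0.001, method: str = "bh") -> "AgeRegressionReport":
        flags = fdr_adjust(self.p_values, alpha=alpha, method=method)
        return AgeRegressionReport(
            slopes=self.slopes, p_values=self.p_values, alpha=alpha, significant=flags
        )


@dataclass
class CvMaeReport:
    fold_maes: np.ndarray  # years
    folds: int
    provenance: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.fold_maes = np.asarray(self.fold_maes, dtype=float)
        if np.any(self.fold_maes < 0):
            raise ValueError("MAE cannot be negative")

    @property
    def mean(self) -> float:
        return float(self.fold_maes.mean())

    @property
    def sd(self) -> float:
        return float(self.fold_maes.std(ddof=1)) if self.fold_maes.size > 1 else 0.0


def per_feature_age_regression(
    M: PopulationMatrix, ages: Sequence[float], features: Optional[FeatureSet] = None
) -> AgeRegressionReport:
    """Simple linear regression of every feature on age, vectorized.

    For each feature: OLS slope with intercept and the two-sided t-test
    p-value for that slope (n - 2 degrees of freedom).  Constant features
    get slope 0 and p = 1 by convention (logged); they carry no age signal.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size != M.n:
        raise ValueError("ages length must match subject count")
    if M.n < 3:
        raise ValueError("need at least 3 subjects for a slope test")
    if np.ptp(ages) == 0:
        raise ValueError("ages must vary")
    x = M.values if features is None else M.values[features.indices, :]
    a = ages - ages.mean()
    ssx = float(a @ a)
    y = x - x.mean(axis=1, keepdims=True)
    slopes = (y @ a) / ssx
    resid = y - np.outer(slopes, a)
    dof = M.n - 2
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(sigma2 / ssx)
    constant = np.ptp(x, axis=1) == 0
    if constant.any():
        logger.warning("%d constant features: slope set to 0, p to 1", int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slopes / se, 0.0)
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    slopes = np.where(constant, 0.0, slopes)
    p = np.where(constant, 1.0, p)
    # a non-constant feature fit exactly (zero residual) is maximally significant
    exact = (~constant) & (se == 0)
    p = np.where(exact, 0.0, p)
    return AgeRegressionReport(slopes=slopes, p_values=p)


def fdr_adjust(p_values: Sequence[float], alpha: float = 0.001, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or Benjamini-Yekutieli) step-up significance flags.

    Returns a boolean array; flags are monotone in p (if p_a <= p_b and b
    is flagged, so is a).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "by"):
        raise ValueError("method must be 'bh' or 'by'")
    sm_method = "fdr_bh" if method == "bh" else "fdr_by"
    flags, _, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return flags


def cv_age_prediction(
    M: PopulationMatrix,
    ages: Sequence[float],
    features: FeatureSet,
    folds: int = 10,
    seed: int = 0,
    ridge_alpha: float = 1.0,
) -> CvMaeReport:
    """K-fold cross-validated MAE of linear age prediction from features.

    Subjects are shuffled by ``seed`` into near-equal folds.  Per fold, a
    least-squares model of age on the restricted features is fit on the
    training folds and scored by MAE on the held-out fold.  When the
    feature count reaches the training size plain OLS is underdetermined,
    so a ridge penalty (fixed ``ridge_alpha``) is used instead.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size != M.n:
        raise ValueError("ages length must match subject count")
    if M.n < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    if len(features) < 1:
        raise ValueError("need at least one feature")
    X = M.values[features.indices, :].T  # subjects x features
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    maes = []
    for train, test in kf.split(X):
        if train.size < 2:
            raise ValueError("fold with fewer than 2 training subjects")
        if X.shape[1] >= train.size:
            model = Ridge(alpha=ridge_alpha)
        else:
            model = LinearRegression()
        model.fit(X[train], ages[train])
        pred = model.predict(X[test])
        maes.append(float(np.abs(pred - ages[test]).mean()))
    return CvMaeReport(
        fold_maes=np.array(maes), folds=folds, provenance=features.provenance, seed=seed
    )


@dataclass
class MaeDistribution:
    set_means: np.ndarray
    k: int
    seed: int

    @property
    def mean(self) -> float:
        return float(self.set_means.mean())

    @property
    def sd(self) -> float:
        return float(self.set_means.std(ddof=1)) if self.set_means.size > 1 else 0.0


def random_set_mae_distribution(
    M: PopulationMatrix,
    ages: Sequence[float],
    k: int,
    n_sets: int,
    folds: int = 10,
    seed: int = 0,
    ridge_alpha: float = 1.0,
) -> MaeDistribution:
    """Distribution of CV-MAE over independent random feature sets.

    Each of ``n_sets`` uniform size-k subsets is scored by
    :func:`cv_age_prediction` with a fold shuffle derived from the master
    seed; returns the per-set mean MAEs.
    """
    if n_sets < 1:
        raise ValueError("need at least one random set")
    rng = np.random.default_rng(seed)
    means = np.empty(n_sets)
    for i in range(n_sets):
        feats = sample_random_features(M.m, k, rng=rng)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        report = cv_age_prediction(
            M, ages, feats, folds=folds, seed=fold_seed, ridge_alpha=ridge_alpha
        )
        means[i] = report.mean
    return MaeDistribution(set_means=means, k=k, seed=seed)
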