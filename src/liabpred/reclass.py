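"""Analytic net reclassification improvement (NRI) and IDI.

Two nested prediction models are represented by the liability variance each
explains.  Conditioning the pair of measurable liabilities on disease status
(Pearson-Aitken selection on the overall liability) gives a bivariate normal
within cases and within non-cases; risk-category transition probabilities are
then bivariate-normal rectangle masses between the liability cutpoints that
map to the category thresholds under each model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .liability import (
    DiseaseModel,
    liability_threshold,
    truncated_moments,
)
from .riskdist import risk_summary

#: requested absolute accuracy of the bivariate-normal rectangle masses
_BVN_ABSEPS = 1e-9


@dataclass(frozen=True)
class NestedModels:
    """Old and new prediction models sharing the same disease.

    ``cov_old_new`` is the covariance between the two measurable liabilities;
    it defaults to ``v_old``, which is exact when the factors added by the
    new model are independent of the old ones.
    """

    k: float
    v_old: float
    v_new: float
    cov_old_new: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"K must be in (0, 1), got {self.k}")
        for name in ("v_old", "v_new"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        full = self.full_covariance()
        if np.linalg.eigvalsh(full).min() < -1e-9:
            raise ValueError(
                "covariance of (overall, old, new) liabilities is not "
                f"positive semidefinite: K={self.k}, v_old={self.v_old}, "
                f"v_new={self.v_new}, cov={self.cov}")

    @property
    def cov(self) -> float:
        return self.v_old if self.cov_old_new is None else self.cov_old_new

    def full_covariance(self) -> np.ndarray:
        """3x3 covariance of (overall, old measurable, new measurable)."""
        return np.array([
            [1.0, self.v_old, self.v_new],
            [self.v_old, self.v_old, self.cov],
            [self.v_new, self.cov, self.v_new],
        ])


def risk_category_cutpoints(
    k: float, v: float, thresholds: Sequence[float]
) -> np.ndarray:
    """Measurable-liability values whose predicted risk equals each threshold.

    ``z_j = T + sqrt(1 - v) * Phi^-1(r_j)`` — inverting the percentile-risk
    map on the liability scale under variance explained ``v``.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0.0) | (thresholds >= 1.0)):
        raise ValueError("risk thresholds must lie strictly inside (0, 1)")
    if np.any(np.diff(thresholds) <= 0.0):
        raise ValueError("risk thresholds must be strictly increasing")
    if v >= 1.0:
        raise ValueError("variance explained must be < 1")
    t = liability_threshold(k)
    return t + np.sqrt(1.0 - v) * stats.norm.ppf(thresholds)


@dataclass(frozen=True)
class BivariateParams:
    mean: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)


def joint_conditional_moments(
    models: NestedModels,
) -> tuple[BivariateParams, BivariateParams]:
    """Bivariate-normal parameters of (old, new) measurable liabilities
    within cases and within controls, by Pearson-Aitken conditioning."""
    a, b, c, d = truncated_moments(models.k)
    v = np.array([models.v_old, models.v_new])
    sigma_m = np.array([[models.v_old, models.cov],
                        [models.cov, models.v_new]])
    case = BivariateParams(mean=a * v, cov=sigma_m - (1.0 - b) * np.outer(v, v))
    ctrl = BivariateParams(mean=c * v, cov=sigma_m - (1.0 - d) * np.outer(v, v))
    for label, par in (("cases", case), ("controls", ctrl)):
        if np.linalg.eigvalsh(par.cov).min() < -1e-9:
            raise ValueError(
                f"conditional covariance within {label} is not positive "
                f"semidefinite for K={models.k}, v_old={models.v_old}, "
                f"v_new={models.v_new}, cov={models.cov}")
    return case, ctrl


def _rect_prob(par: BivariateParams, lo: np.ndarray, hi: np.ndarray) -> float:
    """P(lo < X <= hi) for bivariate normal X, robust to degenerate
    (perfectly correlated) components."""
    s = np.sqrt(np.diag(par.cov))
    if np.any(s <= 0.0):
        # at least one coordinate is a point mass
        inside = True
        for i in range(2):
            if s[i] <= 0.0:
                inside &= lo[i] < par.mean[i] <= hi[i]
        if not inside:
            return 0.0
        # remaining free coordinate(s)
        prob = 1.0
        for i in range(2):
            if s[i] > 0.0:
                prob *= (stats.norm.cdf((hi[i] - par.mean[i]) / s[i])
                         - stats.norm.cdf((lo[i] - par.mean[i]) / s[i]))
        return prob
    rho = par.cov[0, 1] / (s[0] * s[1])
    if abs(rho) > 1.0 - 1e-12:
        # perfectly (anti)correlated: mass lives on a line; reduce to the
        # first coordinate with the second's interval mapped through the line
        sgn = np.sign(rho)
        # X2 = mu2 + sgn*(s2/s1)(X1 - mu1)  =>  interval for X1
        m1, m2 = par.mean
        if sgn > 0:
            lo1 = max(lo[0], m1 + (lo[1] - m2) * s[0] / s[1])
            hi1 = min(hi[0], m1 + (hi[1] - m2) * s[0] / s[1])
        else:
            lo1 = max(lo[0], m1 - (hi[1] - m2) * s[0] / s[1])
            hi1 = min(hi[0], m1 - (lo[1] - m2) * s[0] / s[1])
        if hi1 <= lo1:
            return 0.0
        return float(stats.norm.cdf((hi1 - m1) / s[0])
                     - stats.norm.cdf((lo1 - m1) / s[0]))
    # clip infinities for the numerical integrator
    span = 10.0
    lo_c = np.maximum(lo, par.mean - span * s)
    hi_c = np.minimum(hi, par.mean + span * s)
    if np.any(hi_c <= lo_c):
        return 0.0
    val = stats.multivariate_normal.cdf(
        hi_c, mean=par.mean, cov=par.cov, lower_limit=lo_c,
        abseps=_BVN_ABSEPS, releps=0.0,
    )
    # the integrator can return tiny negatives for far-tail rectangles
    return float(max(val, 0.0))


@dataclass(frozen=True)
class ReclassificationResult:
    """Risk-category transition matrices within cases/controls and the NRI."""

    thresholds: tuple[float, ...]
    case_matrix: np.ndarray = field(repr=False)
    control_matrix: np.ndarray = field(repr=False)

    @property
    def p_up_case(self) -> float:
        return float(np.triu(self.case_matrix, 1).sum())

    @property
    def p_down_case(self) -> float:
        return float(np.tril(self.case_matrix, -1).sum())

    @property
    def p_up_control(self) -> float:
        return float(np.triu(self.control_matrix, 1).sum())

    @property
    def p_down_control(self) -> float:
        return float(np.tril(self.control_matrix, -1).sum())

    @property
    def nri(self) -> float:
        return ((self.p_up_case - self.p_down_case)
                - (self.p_up_control - self.p_down_control))


def reclassification_table(
    models: NestedModels, thresholds: Sequence[float]
) -> ReclassificationResult:
    """Analytic case/control transition matrices across risk categories.

    Categories are half-open ``[lower, upper)``: a risk exactly at a
    threshold belongs to the upper category (measure zero in the continuous
    model, fixed for determinism).
    """
    thresholds = tuple(float(r) for r in thresholds)
    if len(thresholds) < 1:
        raise ValueError("at least one risk threshold is required")
    cuts_old = risk_category_cutpoints(models.k, models.v_old, thresholds)
    cuts_new = risk_category_cutpoints(models.k, models.v_new, thresholds)
    edges_old = np.concatenate([[-np.inf], cuts_old, [np.inf]])
    edges_new = np.concatenate([[-np.inf], cuts_new, [np.inf]])
    case, ctrl = joint_conditional_moments(models)
    n_cat = len(thresholds) + 1

    def matrix(par: BivariateParams) -> np.ndarray:
        m = np.empty((n_cat, n_cat))
        for i in range(n_cat):
            for j in range(n_cat):
                m[i, j] = _rect_prob(
                    par,
                    np.array([edges_old[i], edges_new[j]]),
                    np.array([edges_old[i + 1], edges_new[j + 1]]),
                )
        return m

    return ReclassificationResult(
        thresholds=thresholds,
        case_matrix=matrix(case),
        control_matrix=matrix(ctrl),
    )


def weighted_nri(
    result: ReclassificationResult,
    weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
    category_shift_scores: bool = False,
) -> float:
    """NRI with its four components weighted, optionally scoring transitions
    by the number of categories moved.

    ``weights`` applies to (up|case, down|case, up|control, down|control);
    all-ones without shift scoring reduces to the plain NRI.
    """
    w_uc, w_dc, w_un, w_dn = (float(w) for w in weights)
    n = result.case_matrix.shape[0]
    shift = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    score = shift if category_shift_scores else (shift > 0).astype(float)
    up = np.triu(np.ones((n, n)), 1)
    down = np.tril(np.ones((n, n)), -1)
    uc = float((result.case_matrix * score * up).sum())
    dc = float((result.case_matrix * score * down).sum())
    un = float((result.control_matrix * score * up).sum())
    dn = float((result.control_matrix * score * down).sum())
    return w_uc * uc - w_dc * dc - w_un * un + w_dn * dn


def idi(models: NestedModels) -> float:
    """Integrated discrimination improvement: the difference in
    discrimination slope between the new and old models."""
    slope_new = risk_summary(DiseaseModel(models.k, models.v_new)).discrimination_slope
    slope_old = risk_summary(DiseaseModel(models.k, models.v_old)).discrimination_slope
    return slope_new - slope_old
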