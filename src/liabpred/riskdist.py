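"""Distribution of predicted risks and derived summary indices.

Everything here reduces to integrals of the percentile-to-risk map; all
expectations over the predicted risk R are computed by substitution in
percentile space (``E[h(R)] = int_0^1 h(R(p)) dp``), where the integrand is
smooth, rather than against the risk density g(R), which is unbounded near
the support edges for small variance explained.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate, stats

from .liability import (
    DiseaseModel,
    cumulative_risk,
    percentile_at_risk,
    risk_at_percentile,
)

Group = Literal["population", "cases", "noncases"]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


@dataclass(frozen=True)
class RiskDensity:
    """Density and distribution function of predicted risk for one group."""

    group: Group
    pdf: Callable = field(repr=False)
    cdf: Callable = field(repr=False)
    support: tuple[float, float] = (0.0, 1.0)


def risk_density(model: DiseaseModel, group: Group = "population") -> RiskDensity:
    """Predicted-risk density for the population, cases, or non-cases.

    The population cdf is the percentile map ``F(R) = p(R)``; its derivative
    gives the closed-form pdf.  Case and non-case densities follow by Bayes:
    ``R g(R)/K`` and ``(1-R) g(R)/(1-K)``.
    """
    if model.degenerate:
        raise ValueError(
            "risk distribution is a point mass at K when Vm = 0")
    if group not in ("population", "cases", "noncases"):
        raise ValueError(f"unknown group {group!r}")
    k, vm, t = model.k, model.vm, model.threshold
    s1 = np.sqrt(1.0 - vm)
    sv = np.sqrt(vm)

    def g(r):
        r = np.asarray(r, dtype=float)
        q = stats.norm.ppf(r)
        u = (t + s1 * q) / sv
        out = (s1 / sv) * stats.norm.pdf(u) / stats.norm.pdf(q)
        return float(out) if out.ndim == 0 else out

    def pop_cdf(r):
        return percentile_at_risk(model, r)

    if group == "population":
        return RiskDensity(group=group, pdf=g, cdf=pop_cdf)

    def _int_risk_to(p_hi):
        """int_0^p_hi R(p) dp, vectorised via adaptive quadrature."""
        scalar = np.isscalar(p_hi) or np.ndim(p_hi) == 0
        vals = [
            integrate.quad(lambda p: risk_at_percentile(model, p), 0.0, ph,
                           epsabs=1e-10, limit=200)[0]
            for ph in np.atleast_1d(np.asarray(p_hi, dtype=float))
        ]
        return vals[0] if scalar else np.asarray(vals)

    if group == "cases":
        def pdf(r):
            r = np.asarray(r, dtype=float)
            out = r * g(r) / k
            return float(out) if out.ndim == 0 else out

        def cdf(r):
            p_hi = percentile_at_risk(model, r)
            out = np.asarray(_int_risk_to(p_hi)) / k
            return float(out) if out.ndim == 0 else out
    else:
        def pdf(r):
            r = np.asarray(r, dtype=float)
            out = (1.0 - r) * g(r) / (1.0 - k)
            return float(out) if out.ndim == 0 else out

        def cdf(r):
            p_hi = percentile_at_risk(model, r)
            out = (np.asarray(p_hi) - np.asarray(_int_risk_to(p_hi))) / (1.0 - k)
            return float(out) if out.ndim == 0 else out

    return RiskDensity(group=group, pdf=pdf, cdf=cdf)


def predictiveness_curve(
    model: DiseaseModel, grid: int = 5000
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted risk against risk percentile over an even interior grid.

    Returns the arrays ``(p, R(p))``; monotone increasing in ``p`` whenever
    the model explains any liability variance.
    """
    if grid < 2:
        raise ValueError("grid must be at least 2")
    p = np.linspace(0.0, 1.0, grid + 2)[1:-1]
    return p, np.asarray(risk_at_percentile(model, p))


def proportion_cases_explained(model: DiseaseModel, top_fraction: float) -> float:
    """Fraction of all cases found in the top ``top_fraction`` of the
    population ranked by predicted risk.

    ``(1/K) * int_{1 - top}^{1} R(p) dp``.
    """
    if not 0.0 <= top_fraction <= 1.0:
        raise ValueError("top_fraction must be in [0, 1]")
    if top_fraction == 0.0:
        return 0.0
    if top_fraction == 1.0:
        return 1.0
    if model.degenerate:
        return top_fraction
    val, _ = integrate.quad(
        lambda p: risk_at_percentile(model, p), 1.0 - top_fraction, 1.0,
        epsabs=1e-10, limit=200,
    )
    return float(val / model.k)


@dataclass(frozen=True)
class CasesExplainedCurve:
    """Lorenz-type curve: cases captured vs top population fraction."""

    top_fraction: np.ndarray = field(repr=False)
    cases_explained: np.ndarray = field(repr=False)
    area: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.top_fraction, self.cases_explained])


def cases_explained_curve(
    model: DiseaseModel, grid: int = 5000
) -> CasesExplainedCurve:
    """Proportion of cases explained against the population fraction at
    highest risk, with trapezoidal area.

    The area approximates — but does not equal — the AUC; the two approach
    each other as the outcome becomes rare.
    """
    if grid < 2:
        raise ValueError("grid must be at least 2")
    x = np.linspace(0.0, 1.0, grid + 1)
    if model.degenerate:
        y = x.copy()
    else:
        # proportion of cases above percentile 1-x: (K - I(1-x)) / K
        y = (model.k - cumulative_risk(model, 1.0 - x)) / model.k
        y[0], y[-1] = 0.0, 1.0
    area = float(np.trapezoid(y, x))
    return CasesExplainedCurve(top_fraction=x, cases_explained=y, area=area)


@dataclass(frozen=True)
class RiskSummary:
    """Dispersion and percentile summaries of the predicted-risk distribution."""

    var_risk: float
    var_ratio: float
    mean_risk_cases: float
    mean_risk_noncases: float
    discrimination_slope: float
    risk_at_p: dict[float, float]
    rr_between: float
    range_between: float


def mean_square_risk(model: DiseaseModel) -> float:
    """``E[R^2] = int_0^1 R(p)^2 dp`` by adaptive quadrature."""
    if model.degenerate:
        return model.k ** 2
    val, _ = integrate.quad(
        lambda p: risk_at_percentile(model, p) ** 2, 0.0, 1.0,
        epsabs=1e-12, limit=200,
    )
    return float(val)


def risk_summary(
    model: DiseaseModel, p_low: float = 0.1, p_high: float = 0.9
) -> RiskSummary:
    """Variance of risks, discrimination slope, and percentile contrasts.

    The variance-to-maximum ratio ``var(R) / (K (1-K))`` equals the
    discrimination slope (mean risk in cases minus non-cases) exactly.
    """
    if not 0.0 < p_low < p_high < 1.0:
        raise ValueError("need 0 < p_low < p_high < 1")
    k = model.k
    if model.degenerate:
        return RiskSummary(
            var_risk=0.0, var_ratio=0.0,
            mean_risk_cases=k, mean_risk_noncases=k,
            discrimination_slope=0.0,
            risk_at_p={p_low: k, p_high: k},
            rr_between=1.0, range_between=0.0,
        )
    er2 = mean_square_risk(model)
    var_risk = er2 - k * k
    mean_cases = er2 / k
    mean_noncases = (k - er2) / (1.0 - k)
    r_lo = float(risk_at_percentile(model, p_low))
    r_hi = float(risk_at_percentile(model, p_high))
    return RiskSummary(
        var_risk=float(var_risk),
        var_ratio=float(var_risk / (k * (1.0 - k))),
        mean_risk_cases=float(mean_cases),
        mean_risk_noncases=float(mean_noncases),
        discrimination_slope=float(mean_cases - mean_noncases),
        risk_at_p={p_low: r_lo, p_high: r_hi},
        rr_between=r_hi / r_lo,
        range_between=r_hi - r_lo,
    )
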