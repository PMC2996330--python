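"""Liability-threshold model core.

Disease status is determined by a standard-normal latent liability exceeding
a threshold ``T``.  A measurable component (known risk factors) accounts for a
fraction ``vm`` of the unit liability variance; conditioning on it yields an
absolute disease risk for every percentile of the measurable score.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: below this, the variance explained is treated as exactly zero
#: (constant-risk model) to avoid 0/0 in the percentile-to-risk map.
VM_EPS = 1e-12


def liability_threshold(k: float) -> float:
    """Liability threshold ``T`` such that the standard-normal upper-tail
    mass beyond ``T`` equals the overall disease probability ``k``.

    Parameters
    ----------
    k : float
        Overall probability of disease (lifetime or period risk), in (0, 1).

    Returns
    -------
    float
        ``T = Phi^-1(1 - k)``, evaluated through the tail-safe inverse
        survival function.
    """
    if not 0.0 < k < 1.0:
        raise ValueError(f"disease probability K must be in (0, 1), got {k}")
    return float(stats.norm.isf(k))


@dataclass(frozen=True)
class DiseaseModel:
    """The pair (overall disease probability, liability variance explained).

    Attributes
    ----------
    k : float
        Overall disease probability in (0, 1).
    vm : float
        Proportion of unit liability variance explained by measured factors,
        in [0, 1).
    """

    k: float
    vm: float

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"K must be in (0, 1), got {self.k}")
        if not 0.0 <= self.vm < 1.0:
            raise ValueError(f"Vm must be in [0, 1), got {self.vm}")

    @property
    def threshold(self) -> float:
        """Liability threshold ``T``."""
        return liability_threshold(self.k)

    @property
    def degenerate(self) -> bool:
        """True when the model carries no predictive information (vm ~ 0)."""
        return self.vm < VM_EPS


@dataclass(frozen=True)
class ConditionalMoments:
    """Truncated-normal and selection-adjusted moments given disease status.

    ``mean_overall_*`` / ``var_overall_*`` are the moments of the *overall*
    liability within cases (truncation below ``T``) and controls (truncation
    above ``T``).  ``mean_meas_*`` / ``var_meas_*`` are the moments of the
    *measurable* liability in the same groups, obtained by applying the
    Pearson-Aitken selection formula with covariance ``vm`` between the two
    liabilities.
    """

    mean_overall_case: float
    var_overall_case: float
    mean_overall_control: float
    var_overall_control: float
    mean_meas_case: float
    var_meas_case: float
    mean_meas_control: float
    var_meas_control: float

    @property
    def sd_meas_case(self) -> float:
        return float(np.sqrt(self.var_meas_case))

    @property
    def sd_meas_control(self) -> float:
        return float(np.sqrt(self.var_meas_control))


def truncated_moments(k: float) -> tuple[float, float, float, float]:
    """Closed-form moments of a standard normal truncated at ``T = isf(k)``.

    Returns ``(a, b, c, d)``: mean and variance above the threshold (cases),
    then mean and variance below it (controls).
    """
    t = liability_threshold(k)
    phi_t = stats.norm.pdf(t)
    a = phi_t / k
    b = 1.0 + t * a - a * a
    c = -phi_t / (1.0 - k)
    d = 1.0 + t * c - c * c
    return a, b, c, d


def conditional_moments(model: DiseaseModel) -> ConditionalMoments:
    """Case/control moments of overall and measurable liability.

    Applies the Pearson-Aitken selection formula: selecting on disease status
    truncates the overall liability, which shifts the measurable liability by
    the regression coefficient ``vm`` and shrinks its variance by
    ``(1 - b) vm^2`` (cases) or ``(1 - d) vm^2`` (controls).
    """
    a, b, c, d = truncated_moments(model.k)
    vm = model.vm
    return ConditionalMoments(
        mean_overall_case=a,
        var_overall_case=b,
        mean_overall_control=c,
        var_overall_control=d,
        mean_meas_case=a * vm,
        var_meas_case=vm * (1.0 - (1.0 - b) * vm),
        mean_meas_control=c * vm,
        var_meas_control=vm * (1.0 - (1.0 - d) * vm),
    )


def risk_at_percentile(model: DiseaseModel, p):
    """Absolute disease risk at percentile ``p`` of measurable liability.

    ``R(p) = Sf((T - sqrt(vm) * Phi^-1(p)) / sqrt(1 - vm))`` where ``Sf`` is
    the standard-normal survival function.  Accepts scalars or arrays; strict
    domain ``0 < p < 1``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("percentile p must lie strictly inside (0, 1)")
    if model.degenerate:
        out = np.full_like(p, model.k)
        return float(out) if out.ndim == 0 else out
    t = model.threshold
    z = np.sqrt(model.vm) * stats.norm.ppf(p)
    r = stats.norm.sf((t - z) / np.sqrt(1.0 - model.vm))
    return float(r) if r.ndim == 0 else r


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)
_Z_SPAN = 9.5  # standard-normal mass beyond +-9.5 is ~1e-21


def cumulative_risk(model: DiseaseModel, p):
    """``I(p) = int_0^p R(u) du`` for scalar or array ``p`` in [0, 1].

    Evaluated by substitution ``u = Phi(z)`` so the integrand
    ``Sf((T - sqrt(vm) z)/sqrt(1-vm)) * phi(z)`` is analytic on the whole
    line (the percentile-space integrand has endpoint singularities in its
    higher derivatives); composite Gauss-Legendre on a fine z-grid gives
    near machine precision.  ``I(1) = K``.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0.0) | (p_arr > 1.0)):
        raise ValueError("p must lie in [0, 1]")
    if model.degenerate:
        out = model.k * p_arr
        return float(out) if out.ndim == 0 else out
    t = model.threshold
    sv = np.sqrt(model.vm)
    s1 = np.sqrt(1.0 - model.vm)
    z_pts = np.clip(stats.norm.ppf(np.clip(p_arr, 1e-300, 1.0 - 1e-16)),
                    -_Z_SPAN, _Z_SPAN)
    grid = np.union1d(np.atleast_1d(z_pts),
                      np.linspace(-_Z_SPAN, _Z_SPAN, 1501))
    lo, hi = grid[:-1], grid[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = stats.norm.sf((t - sv * nodes) / s1) * stats.norm.pdf(nodes)
    seg = (vals * _GL_WEIGHTS[None, :]).sum(axis=1) * half
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = cum[np.searchsorted(grid, z_pts)]
    return float(out) if np.ndim(p) == 0 else out


def percentile_at_risk(model: DiseaseModel, r):
    """Percentile of measurable liability whose predicted risk equals ``r``.

    Exact inverse of :func:`risk_at_percentile`:
    ``p = Phi((T + sqrt(1 - vm) * Phi^-1(r)) / sqrt(vm))``.
    Undefined for a constant-risk model (``vm = 0``).
    """
    if model.degenerate:
        raise ValueError("percentile_at_risk undefined when Vm = 0 "
                         "(risk is constant at K)")
    r = np.asarray(r, dtype=float)
    if np.any((r <= 0.0) | (r >= 1.0)):
        raise ValueError("risk must lie strictly inside (0, 1)")
    t = model.threshold
    p = stats.norm.cdf(
        (t + np.sqrt(1.0 - model.vm) * stats.norm.ppf(r)) / np.sqrt(model.vm)
    )
    return float(p) if p.ndim == 0 else p
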