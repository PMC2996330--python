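"""Classification tables, ROC curves and analytic AUC.

A "test positive" at percentile cutoff ``c`` means the measurable liability
exceeds its ``c``-th percentile.  The true-positive cell is the integral of
the predicted risk over percentiles above the cutoff; the remaining cells
follow from the 2x2 margins (prevalence ``K`` on one axis, ``1 - c`` on the
other).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .liability import (
    DiseaseModel,
    conditional_moments,
    cumulative_risk,
    risk_at_percentile,
)

# Gauss-Legendre panel used for vectorised cumulative integration of R(p).
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(12)


def true_positive_fraction(model: DiseaseModel, c: float) -> float:
    """Population fraction of true positives at percentile cutoff ``c``.

    ``TP(c) = int_c^1 R(p) dp`` by adaptive quadrature in percentile space
    (the risk density can spike near the support edges, but R(p) is smooth).
    """
    if not 0.0 < c < 1.0:
        raise ValueError(f"cutoff c must be in (0, 1), got {c}")
    if model.degenerate:
        return model.k * (1.0 - c)
    val, _ = integrate.quad(
        lambda p: risk_at_percentile(model, p), c, 1.0,
        epsabs=1e-9, limit=200,
    )
    return float(val)


@dataclass(frozen=True)
class ClassificationTable:
    """2x2 table of population fractions at a percentile cutoff."""

    cutoff: float
    tp: float
    fp: float
    fn: float
    tn: float
    k: float

    @property
    def sensitivity(self) -> float:
        return self.tp / self.k

    @property
    def specificity(self) -> float:
        return self.tn / (1.0 - self.k)

    @property
    def ppv(self) -> float:
        return self.tp / (1.0 - self.cutoff)

    @property
    def npv(self) -> float:
        return self.tn / self.cutoff


def classification_table(model: DiseaseModel, c: float) -> ClassificationTable:
    """All four cells of the 2x2 classification table at cutoff ``c``."""
    tp = true_positive_fraction(model, c)
    fn = model.k - tp
    fp = (1.0 - c) - tp
    tn = c - fn
    return ClassificationTable(cutoff=c, tp=tp, fp=fp, fn=fn, tn=tn, k=model.k)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve as ordered (FPR, TPR) points with trapezoidal area."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _tp_on_grid(model: DiseaseModel, cutoffs: np.ndarray) -> np.ndarray:
    """TP(c) = K - I(c) on a cutoff grid, from the exact cumulative risk."""
    if model.degenerate:
        return model.k * (1.0 - cutoffs)
    total = cumulative_risk(model, 1.0)
    return total - cumulative_risk(model, cutoffs)


def roc_curve(model: DiseaseModel, n_cutoffs: int = 5000) -> RocCurve:
    """ROC curve over equally spaced interior percentile cutoffs.

    ``n_cutoffs`` interior cutoffs are used and the exact endpoints (0, 0)
    and (1, 1) appended; the area is computed by trapezoidal integration.
    """
    if n_cutoffs < 2:
        raise ValueError("n_cutoffs must be at least 2")
    cutoffs = np.linspace(0.0, 1.0, n_cutoffs + 2)[1:-1]
    tp = _tp_on_grid(model, cutoffs)
    sens = tp / model.k
    fp = (1.0 - cutoffs) - tp
    fpr = fp / (1.0 - model.k)
    # cutoffs ascending -> fpr descending; flip to ascending and add endpoints
    fpr = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def auc_exact(model: DiseaseModel, n_intervals: int = 2000) -> float:
    """Exact AUC from the closed-form double integral.

    ``AUC = (1 / (K (1 - K))) * int_0^1 TP(c) (1 - R(c)) dc`` with
    ``TP(c) = int_c^1 R(p) dp``, evaluated by a vectorised composite
    Gauss-Legendre scheme on a uniform partition of percentile space (the
    integrand is smooth there).
    """
    if model.degenerate:
        return 0.5
    k = model.k
    # cosine-graded partition: clusters nodes near 0 and 1 where higher
    # derivatives of R(p) blow up
    edges = 0.5 * (1.0 - np.cos(np.pi * np.linspace(0.0, 1.0, n_intervals + 1)))
    lo, hi = edges[:-1], edges[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = mid[:, None] + half[:, None] * _GL_NODES[None, :]  # (N, g)

    seg = (np.asarray(risk_at_percentile(model, nodes))
           * _GL_WEIGHTS[None, :]).sum(axis=1) * half
    # TP at the right edge of each interval: sum of all later segments
    tp_right = np.concatenate([np.cumsum(seg[::-1])[::-1][1:], [0.0]])

    # TP at each outer node: tail beyond its interval plus the remainder of
    # the interval, int_x^hi R dp, by a nested GL panel per node
    in_half = 0.5 * (hi[:, None] - nodes)                       # (N, g)
    in_mid = 0.5 * (hi[:, None] + nodes)
    in_pts = in_mid[..., None] + in_half[..., None] * _GL_NODES  # (N, g, g)
    in_vals = np.asarray(risk_at_percentile(model, in_pts))
    tp_nodes = tp_right[:, None] + (in_vals * _GL_WEIGHTS).sum(axis=2) * in_half

    outer = (1.0 - np.asarray(risk_at_percentile(model, nodes))) * tp_nodes
    val = float(((outer * _GL_WEIGHTS[None, :]).sum(axis=1) * half).sum())
    return val / (k * (1.0 - k))


def auc_binormal(model: DiseaseModel, equal_variance: bool = True) -> float:
    """Binormal approximation to the AUC.

    Assumes the measurable liability is normal within cases and controls,
    with moments from the Pearson-Aitken selection formula.  With
    ``equal_variance`` both group variances are taken equal to the population
    variance of the measurable liability (``vm``), giving the
    spreadsheet-friendly form ``Phi(delta / sqrt(2 vm))``; otherwise the root
    of the summed case/control variances is used.
    """
    if model.degenerate:
        return 0.5
    m = conditional_moments(model)
    delta = m.mean_meas_case - m.mean_meas_control
    if equal_variance:
        denom = np.sqrt(2.0 * model.vm)
    else:
        denom = np.sqrt(m.var_meas_case + m.var_meas_control)
    return float(stats.norm.cdf(delta / denom))


def rates_at_risk_threshold(
    model: DiseaseModel, r_star: float
) -> tuple[float, float]:
    """Approximate (TPR, FPR) for calling "high risk" above absolute risk
    ``r_star``, via the binormal within-group liability distributions."""
    if model.degenerate:
        raise ValueError("rates undefined for Vm = 0 (risk constant at K)")
    if not 0.0 < r_star < 1.0:
        raise ValueError("risk threshold must be in (0, 1)")
    z_star = model.threshold + np.sqrt(1.0 - model.vm) * stats.norm.ppf(r_star)
    m = conditional_moments(model)
    tpr = stats.norm.sf((z_star - m.mean_meas_case) / m.sd_meas_case)
    fpr = stats.norm.sf((z_star - m.mean_meas_control) / m.sd_meas_control)
    return float(tpr), float(fpr)
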