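"""Metric reports: every index of the analytic framework in one mapping.

Reports echo their inputs so each number can be recomputed by direct library
calls, and serialise losslessly to JSON.
"""
from __future__ import annotations

import datetime
import hashlib
from pathlib import Path

from . import __version__
from .liability import DiseaseModel
from .riskdist import (
    cases_explained_curve,
    proportion_cases_explained,
    risk_summary,
)
from .roc import auc_binormal, auc_exact, roc_curve


def panel_digest(path: str | Path) -> str:
    """SHA-256 digest of a panel file, for report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_metric_report(
    model: DiseaseModel,
    p_low: float = 0.1,
    p_high: float = 0.9,
    top_fractions: tuple[float, ...] = (0.1, 0.2, 0.5),
    provenance: str = "analytic",
    panel_sha256: str | None = None,
) -> dict:
    """All predictive indices for one (K, Vm) model as a JSON-ready dict."""
    summary = risk_summary(model, p_low=p_low, p_high=p_high)
    report = {
        "inputs": {
            "K": model.k,
            "Vm": model.vm,
            "p_low": p_low,
            "p_high": p_high,
            **({"panel_sha256": panel_sha256} if panel_sha256 else {}),
        },
        "auc_exact": auc_exact(model),
        "auc_curve_5000": roc_curve(model, 5000).auc,
        "auc_binormal_equal_var": auc_binormal(model, equal_variance=True),
        "auc_binormal_unequal_var": auc_binormal(model, equal_variance=False),
        "proportion_cases_explained": {
            str(f): proportion_cases_explained(model, f) for f in top_fractions
        },
        "cases_explained_area": cases_explained_curve(model).area,
        "var_risk": summary.var_risk,
        "var_ratio": summary.var_ratio,
        "mean_risk_cases": summary.mean_risk_cases,
        "mean_risk_noncases": summary.mean_risk_noncases,
        "discrimination_slope": summary.discrimination_slope,
        "risk_at_p": {str(p): r for p, r in summary.risk_at_p.items()},
        "rr_between": summary.rr_between,
        "range_between": summary.range_between,
        "provenance": provenance,
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return report


def format_text_report(report: dict, digits: int = 4) -> str:
    """Aligned fixed-precision text rendering of a report dict."""
    lines = []

    def add(label: str, value) -> None:
        lines.append(f"{label:<34s}{value}")

    def num(x: float) -> str:
        return f"{x:.{digits}g}"

    inputs = report.get("inputs", {})
    for key, val in inputs.items():
        add(key, val)
    for key, val in report.items():
        if key in ("inputs", "provenance", "tool_version", "timestamp"):
            continue
        if isinstance(val, dict):
            for sub, subval in val.items():
                add(f"{key}[{sub}]", num(subval))
        elif isinstance(val, float):
            add(key, num(val))
        else:
            add(key, val)
    add("provenance", report.get("provenance", ""))
    return "\n".join(lines) + "\n"
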