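"""Six-panel figure set visualising a risk model.

Panels: ROC curve, predictiveness curve, cdf and pdf of predicted risks,
population vs case densities, and the cases-explained (Lorenz-type) curve.
All grids are fixed, so repeated renders of the same model are deterministic.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .liability import DiseaseModel, risk_at_percentile  # noqa: E402
from .riskdist import (  # noqa: E402
    cases_explained_curve,
    predictiveness_curve,
    risk_density,
)
from .roc import roc_curve  # noqa: E402

# fixed hash salt so SVG element ids do not vary between renders
matplotlib.rcParams["svg.hashsalt"] = "liabpred"

_GRID = 2000


def _save(fig, path: Path, fmt: str) -> None:
    kwargs = {"metadata": {"Date": None}} if fmt == "svg" else {}
    fig.savefig(path, format=fmt, **kwargs)
    plt.close(fig)


def render_figures(
    model: DiseaseModel, outdir: str | Path, fmt: str = "png"
) -> list[Path]:
    """Render the six diagnostic panels into ``outdir``; returns the paths."""
    if fmt not in ("png", "svg"):
        raise ValueError(f"unsupported figure format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    # A: ROC curve
    roc = roc_curve(model, n_cutoffs=_GRID)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, color="tab:blue")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"ROC curve (AUC = {roc.auc:.3f})")
    paths.append(outdir / f"roc.{fmt}")
    _save(fig, paths[-1], fmt)

    # B: predictiveness curve
    p, r = predictiveness_curve(model, grid=_GRID)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(p, r, color="tab:green")
    ax.axhline(model.k, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Risk percentile")
    ax.set_ylabel("Predicted risk")
    ax.set_title("Predictiveness curve")
    paths.append(outdir / f"predictiveness.{fmt}")
    _save(fig, paths[-1], fmt)

    if model.degenerate:
        r_grid = np.array([model.k])
        dens = cdf_vals = pdf_vals = cases_pdf = None
    else:
        lo = float(risk_at_percentile(model, 1e-4))
        hi = float(risk_at_percentile(model, 1.0 - 1e-4))
        r_grid = np.linspace(lo, hi, _GRID)
        dens = risk_density(model, "population")
        pdf_vals = dens.pdf(r_grid)
        cdf_vals = dens.cdf(r_grid)
        cases_pdf = risk_density(model, "cases").pdf(r_grid)

    # C: cdf of predicted risks
    fig, ax = plt.subplots(figsize=(5, 5))
    if cdf_vals is not None:
        ax.plot(r_grid, cdf_vals, color="tab:blue")
    else:
        ax.axvline(model.k, color="tab:blue")
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Cumulative probability")
    ax.set_title("CDF of predicted risks")
    paths.append(outdir / f"cdf.{fmt}")
    _save(fig, paths[-1], fmt)

    # D: pdf of predicted risks
    fig, ax = plt.subplots(figsize=(5, 5))
    if pdf_vals is not None:
        ax.plot(r_grid, pdf_vals, color="tab:blue")
    else:
        ax.axvline(model.k, color="tab:blue")
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Density")
    ax.set_title("PDF of predicted risks")
    paths.append(outdir / f"pdf.{fmt}")
    _save(fig, paths[-1], fmt)

    # E: population vs case densities
    fig, ax = plt.subplots(figsize=(5, 5))
    if pdf_vals is not None:
        ax.plot(r_grid, pdf_vals, color="tab:blue", label="population")
        ax.plot(r_grid, cases_pdf, color="tab:green", ls=":", label="cases")
        ax.legend()
    else:
        ax.axvline(model.k, color="tab:blue")
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Density")
    ax.set_title("Risk densities: population and cases")
    paths.append(outdir / f"density_cases.{fmt}")
    _save(fig, paths[-1], fmt)

    # F: cases-explained curve
    curve = cases_explained_curve(model, grid=_GRID)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.top_fraction, curve.cases_explained, color="tab:red")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("Proportion of population at highest risk")
    ax.set_ylabel("Proportion of cases explained")
    ax.set_title(f"Cases explained (area = {curve.area:.3f})")
    paths.append(outdir / f"cases_explained.{fmt}")
    _save(fig, paths[-1], fmt)

    return paths
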