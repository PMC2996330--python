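"""Variant panels: allele frequencies and odds ratios to liability variance.

A panel row is a biallelic locus with a risk-allele frequency and per-allele
odds ratio.  Odds ratios are first converted to genotype-specific absolute
risks consistent with the overall disease probability (the odds ratio is not
a risk ratio unless the disease is rare); each genotype's absolute risk then
maps to a shift of the liability threshold, and the per-locus liability
variance is the variance of those shifts under Hardy-Weinberg genotype
frequencies.  Loci are treated as independent, so variances add.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .liability import liability_threshold

_REQUIRED_COLUMNS = ("id", "raf", "or")


@dataclass(frozen=True)
class Variant:
    """A biallelic risk locus."""

    id: str
    raf: float
    or_het: float
    or_hom: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.raf < 1.0:
            raise ValueError(
                f"variant {self.id!r}: risk-allele frequency must be in "
                f"(0, 1), got {self.raf}")
        if self.or_het <= 0.0:
            raise ValueError(
                f"variant {self.id!r}: odds ratio must be positive, "
                f"got {self.or_het}")
        if self.or_hom is not None and self.or_hom <= 0.0:
            raise ValueError(
                f"variant {self.id!r}: homozygote odds ratio must be "
                f"positive, got {self.or_hom}")

    @property
    def odds_ratios(self) -> np.ndarray:
        """Per-genotype odds ratios (0, 1, 2 risk alleles), reference = 1.

        The homozygote defaults to ``or_het ** 2`` (multiplicative model,
        additive on the log-odds scale).
        """
        hom = self.or_het ** 2 if self.or_hom is None else self.or_hom
        return np.array([1.0, self.or_het, hom])

    @property
    def genotype_freqs(self) -> np.ndarray:
        """Hardy-Weinberg genotype frequencies for 0/1/2 risk alleles."""
        q = self.raf
        return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


@dataclass(frozen=True)
class GenotypeRisks:
    """Absolute and relative risks per genotype, consistent with prevalence."""

    baseline_risk: float
    absolute_risks: np.ndarray
    relative_risks: np.ndarray


def load_panel(path: str | Path) -> list[Variant]:
    """Read a variant panel from delimited text.

    The dialect is chosen by extension (``.csv`` comma, anything else tab);
    the header must contain ``id``, ``raf``, ``or`` and may contain
    ``or_hom``.  Malformed rows raise with the offending row named.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no variants")
    variants = []
    for idx, row in df.iterrows():
        try:
            variants.append(Variant(
                id=str(row["id"]),
                raf=float(row["raf"]),
                or_het=float(row["or"]),
                or_hom=float(row["or_hom"]) if "or_hom" in df.columns
                and pd.notna(row.get("or_hom")) else None,
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, row {idx + 1}: {exc}") from exc
    return variants


def write_panel(variants: list[Variant], path: str | Path) -> None:
    """Write a panel back to delimited text (inverse of :func:`load_panel`)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame({
        "id": [v.id for v in variants],
        "raf": [v.raf for v in variants],
        "or": [v.or_het for v in variants],
    })
    if any(v.or_hom is not None for v in variants):
        df["or_hom"] = [
            v.or_het ** 2 if v.or_hom is None else v.or_hom for v in variants
        ]
    df.to_csv(path, sep=sep, index=False)


def synthetic_panel(
    n_loci: int,
    seed: int,
    raf_range: tuple[float, float] = (0.05, 0.95),
    or_range: tuple[float, float] = (1.05, 1.35),
) -> list[Variant]:
    """Seeded random panel with uniform allele frequencies and log-uniform
    odds ratios — a fixture generator for tests and simulations."""
    rng = np.random.default_rng(seed)
    rafs = rng.uniform(*raf_range, size=n_loci)
    ors = np.exp(rng.uniform(np.log(or_range[0]), np.log(or_range[1]),
                             size=n_loci))
    return [
        Variant(id=f"locus{i + 1}", raf=float(q), or_het=float(o))
        for i, (q, o) in enumerate(zip(rafs, ors))
    ]


def or_to_genotype_risks(variant: Variant, k: float) -> GenotypeRisks:
    """Convert per-genotype odds ratios to absolute and relative risks.

    Solves for the baseline (reference-genotype) risk ``P0`` such that the
    genotype risks implied by ``odds_g = OR_g * P0/(1-P0)`` average to the
    overall disease probability ``k`` under Hardy-Weinberg weights.  In the
    rare-disease limit the relative risks converge to the odds ratios.
    """
    if not 0.0 < k < 1.0:
        raise ValueError(f"K must be in (0, 1), got {k}")
    freqs = variant.genotype_freqs
    ors = variant.odds_ratios

    def mean_risk(p0: float) -> float:
        odds = ors * p0 / (1.0 - p0)
        return float(np.dot(freqs, odds / (1.0 + odds))) - k

    lo, hi = 1e-15, 1.0 - 1e-15
    if mean_risk(lo) > 0.0 or mean_risk(hi) < 0.0:
        raise ValueError(
            f"variant {variant.id!r}: no baseline risk in (0, 1) yields "
            f"mean risk {k}")
    p0 = optimize.brentq(mean_risk, lo, hi, xtol=1e-15, rtol=8.9e-16)
    odds = ors * p0 / (1.0 - p0)
    risks = odds / (1.0 + odds)
    return GenotypeRisks(
        baseline_risk=float(p0),
        absolute_risks=risks,
        relative_risks=risks / risks[0],
    )


def locus_variance(variant: Variant, k: float) -> float:
    """Liability variance contributed by a single locus.

    Each genotype's absolute risk ``P_g`` corresponds to a mean liability
    shift ``mu_g = T - Phi^-1(1 - P_g)`` against the population threshold;
    the locus variance is the HWE-weighted variance of the shifts.
    """
    t = liability_threshold(k)
    risks = or_to_genotype_risks(variant, k).absolute_risks
    mu = t - stats.norm.isf(risks)
    freqs = variant.genotype_freqs
    mean = float(np.dot(freqs, mu))
    return float(np.dot(freqs, mu ** 2) - mean ** 2)


def variance_explained(panel: list[Variant], k: float) -> float:
    """Total liability variance explained by a panel of independent loci."""
    vm = float(sum(locus_variance(v, k) for v in panel))
    if vm >= 1.0:
        raise ValueError(
            f"panel explains variance {vm:.4f} >= 1: liability model "
            "breakdown (effect sizes too large for this framework)")
    return vm
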