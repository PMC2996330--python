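# liabpred

Analytic evaluation of (genetic) risk-prediction models under the
liability-threshold framework.

Given an overall disease probability `K` and the proportion of liability
variance explained by measured factors `Vm` — or a variant panel of risk
allele frequencies and odds ratios from which `Vm` is derived — `liabpred`
computes, in closed form or by deterministic quadrature:

* the full 2×2 classification table at any percentile cutoff, the ROC curve
  and the exact AUC, plus two binormal approximations;
* the distribution of predicted risks (population / cases / non-cases), the
  predictiveness curve, risk at any percentile, and percentile contrasts
  (relative risk and range between e.g. the 10th and 90th percentiles);
* the proportion of cases occurring in the top fraction of the population by
  predicted risk, and the Lorenz-type cases-explained curve and its area;
* variance of predicted risks, its ratio to the maximum `K(1−K)`, mean risks
  in cases/non-cases and the discrimination slope;
* analytic net reclassification improvement (NRI) across arbitrary risk
  categories for nested models via bivariate-normal conditioning, weighted
  and shift-scored variants, and the integrated discrimination improvement
  (IDI);
* a seeded Monte-Carlo cohort simulator under the multiplicative-odds
  logistic model, with empirical counterparts of every metric (rank AUC,
  empirical NRI from refitted nested logistic models, …) serving as a
  validation oracle.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` reproduces the published reference tables
(analytic index grid, reclassification-improvement grid, nine-disease table)
and validates the simulator against the analytic values at N=10⁵. Set
`LIABPRED_FULL=1` to run the simulation checks at the original N=10⁶ scale.

## Command line

```sh
# predictive indices for one model
liabpred metrics --k 0.005 --vm 0.05 --out report.json

# ... or derive Vm from a variant panel (TSV/CSV: id, raf, or[, or_hom])
liabpred metrics --k 0.127 --panel breast.tsv

# reclassification improvement between nested models
liabpred nri --k 0.05 --v-old 0.05 --v-new 0.1 --thresholds 0.06,0.2

# variance explained by a panel
liabpred panel --panel panel.tsv --k 0.005

# simulate a cohort and report empirical metrics
liabpred simulate --k 0.01 --n 100000 --seed 1 --n-loci 30 --out sim.json

# six-panel figure set (ROC, predictiveness, cdf, pdf, densities, Lorenz)
liabpred figures --k 0.127 --vm 0.057 --outdir figs --format png
```

Exit codes: 0 success, 2 usage error, 1 computation failure. `metrics` and
`nri` accept `--config file.yaml` with keys mirroring the flags (explicit
flags win).

## Library example

```python
from liabpred import DiseaseModel, auc_exact, risk_summary

model = DiseaseModel(k=0.005, vm=0.05)
print(auc_exact(model))                      # 0.679
print(risk_summary(model).rr_between)        # risk ratio, 90th vs 10th pct
```
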