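# endosim

Individual-level microsimulation of **extended adjuvant endocrine therapy
(5 vs 10 years)** for women with estrogen-receptor-positive (ER+),
non-metastatic breast cancer. The package is aimed at health-economic and
cancer-modelling researchers who want a seeded, testable simulator of the
lifetime benefit/harm arithmetic behind treatment-duration decisions:
breast-cancer mortality, life-years (LYs), quality-adjusted life-years
(QALYs), discounting, adverse events, and one-/two-way sensitivity analysis.

## Model

For each simulated woman (age at diagnosis 25–79, stage 1–3, with stages
1/2a node-negative and 2b/3 node-positive) the simulator realizes **paired
life histories** under the 5-year and 10-year strategies using common random
numbers (CRN):

* **Baseline breast-cancer mortality.** A lifetime cumulative hazard
  Λ<sub>total</sub> per stratum (ages 25–49 / 50–79 × nodal status), spread
  over the first 25 post-diagnosis years by a truncated-Weibull time shape
  (no BC death occurs after year 25). A latent exponential draw E decides
  whether (E < effective cumulative hazard) and when (inverse transform)
  she dies of breast cancer. Λ<sub>total</sub> is **calibrated** so the
  5-year arm's simulated crude lifetime P(BC death) matches the reference
  levels (11.91% ages 25–49; 10.20% ages 50–79), and the time shape is
  calibrated to the share of the 10-vs-5 difference accrued by year 15.
* **Treatment effects.** Strategy-level hazard ratios (HR₅, HR₁₀ vs no
  endocrine therapy) by age band and stage group — tamoxifen 0.70/0.54
  (stage 1) and 0.66/0.50 (stages 2/3, with ovarian suppression if
  node-positive) for ages 25–49; aromatase inhibitor 0.55/0.54 for ages
  50–79 — are converted to piecewise hazard multipliers. Both arms share
  the first-5-year multiplier; the 10-year arm's tail multiplier on (5, 25]
  solves m·(Λ₂₅−Λ₅) = HR₁₀·Λ₂₅ − HR₅·Λ₅ so its lifetime effect equals HR₁₀.
* **Competing mortality.** Other-cause death ages from a Gompertz–Makeham
  life table (synthetic approximation to U.S. female cohort mortality),
  inverse-sampled conditional on survival to diagnosis.
* **Adverse events and QALYs.** Grade 3–4 events (stroke, pulmonary
  embolus, new cardiac condition, fracture, endometrial cancer,
  osteoporosis) and pooled grade 1–2 symptoms are sampled from cumulative
  per-regimen probabilities; each becomes a multiplicative utility
  decrement over its stated duration. Utility at time t is
  age-band utility × stage utility × active toxicity multipliers, and
  QALYs integrate this exactly with continuous 3%/year discounting.

## Worked example

```python
import endosim as es

cfg = es.default_scenario()           # all published inputs, 100% completion
cfg.calibration.n_cal = 200_000
model = es.calibrate_scenario(cfg)    # calibrate baseline mortality

cfg.cohort.age_range = (25.0, 49.0)   # tamoxifen-age cohort
cfg.n_women = 200_000
res = es.run_simulation(cfg, model)
print(res.comparison_table("25-49").to_string(index=False))
```

prints

```
                outcome  5 years  10 years  difference
Breast cancer mortality    11.91      9.29        2.62
       Undiscounted LYs    33.25     33.97        0.72
         Discounted LYs    19.44     19.79        0.34
     Undiscounted QALYs    23.10     23.52        0.42
       Discounted QALYs    13.70     13.89        0.18
```

Reading: extending tamoxifen from 5 to 10 years cuts the lifetime
probability of breast-cancer death from 11.91% to 9.29% (2.62 percentage
points), worth 0.72 undiscounted life-years per woman; adverse events and
3% discounting shrink the net gain to 0.18 discounted QALYs (~66 days of
perfect health). Absolute LY/QALY *levels* depend on the synthetic life
table and are approximate; the arm *differences* are the calibrated
quantities. For women 50–79 on aromatase inhibitors the same computation
yields a small mortality benefit (≈0.15 points) that is outweighed by
adverse events (≈−0.04 discounted QALYs).

A command-line interface wraps the same machinery:

```bash
endosim run -n 200000 --seed 12345 --out out/          # comparison tables
endosim sensitivity -n 50000 --out out/                # tornado table
endosim validate --set discount_rate=0.0               # config checking
```

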