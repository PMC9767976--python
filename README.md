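# psmcea

Partitioned-survival cost-effectiveness analysis in Python, built around the
cost-utility evaluation of first-line **sintilimab + cisplatin/paclitaxel
versus chemotherapy alone** in advanced or metastatic esophageal squamous cell
carcinoma (ORIENT-15 trial populations), from the Chinese healthcare-system
perspective.

The package is a general toolkit for this class of models — health-economics
analysts can swap in their own survival parameters, digitized Kaplan–Meier
curves and cost/utility tables — and it ships the complete base case of the
published sintilimab evaluation as a worked, tested fixture.

## The model

A three-state **partitioned survival model** (PSM) with mutually exclusive
states: progression-free (PFS), progressed disease (PD) and death.  Occupancy
is read directly off two parametric curves per arm,

```
pfs(t) = S_PFS(t),   pd(t) = S_OS(t) − S_PFS(t),   dead(t) = 1 − S_OS(t),
```

on a 3-week cycle grid that ends when 99 % of the cohort has died (capped at
30 years).  Six candidate distributions (exponential, Weibull, Gompertz,
lognormal, log-logistic, generalized gamma) are fitted to right-censored data
by maximum likelihood, ranked by AIC/BIC, and pseudo individual-patient data
can be reconstructed from digitized published curves when no IPD exists.
Costs (drug acquisition by dose and pack price, administration, routine
follow-up/labs/imaging, best supportive care, subsequent docetaxel, one-off
serious-adverse-event costs) and QALYs (utilities 0.741 / 0.581 for PFS / PD,
first-cycle AE disutilities) accrue against the discounted trace (5 %/year),
yielding the incremental cost-effectiveness ratio

```
ICER = ΔCost / ΔQALY,
```

judged against a willingness-to-pay threshold of 3 × per-capita GDP
(3 × 12,551.50 = 37,654.50 US$/QALY).  One-way (tornado) and probabilistic
(1,000-iteration Monte-Carlo, beta utilities / gamma costs) sensitivity
analyses quantify uncertainty, the latter summarized as a cost-effectiveness
acceptability curve (CEAC).

## Worked example

```bash
psmcea run --population overall --out results/overall
```

prints (and exports as schema-versioned CSVs plus a manifest):

```
population=overall time_grid=reference
  sintilimab_chemo: cost=14,273.20 US$  LY=1.40  QALY=0.93
  chemo: cost=7,797.96 US$  LY=1.05  QALY=0.68
  incremental cost=6,475.24 US$  dQALY=0.25  ICER=25,404.58 US$/QALY
```

The combination buys about a quarter of a quality-adjusted life-year at about
25.4 k US$ per QALY — under the 37,654.50 US$/QALY threshold, so it is
cost-effective in the base case.  The same library call is available in
Python:

```python
from psmcea import CEAEvaluator, orient15_economics, orient15_survival

ev = CEAEvaluator(orient15_survival("overall"), orient15_economics(),
                  wtp=37654.50, time_grid="reference")
res = ev.run()
print(res.icer)
```

Add `--population cps_ge_10` for the PD-L1 CPS ≥ 10 subgroup (ICER ≈
30.2 k US$/QALY), `psmcea psa --seed 1` for the probabilistic analysis, and
`psmcea owsa` for the tornado table (its two dominant drivers are the PFS
utility and the sintilimab price).  `psmcea simulate` writes synthetic
digitized-curve CSVs that `survival_source: refit_from_curves` can consume,
which exercises the digitize → reconstruct → refit → select path end to end.

Note on conventions: `time_grid="reference"` reproduces the published totals
by mirroring the original spreadsheet's time bookkeeping;
`time_grid="calendar"` is the faithful 21-day grid recommended for new
analyses.  `docs/methods.md` explains both, every costing default, and the
known residual discrepancies.

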