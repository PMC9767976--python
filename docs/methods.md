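# Methods

This note documents the model implemented in `psmcea`, the defaults it ships,
the conventions it had to choose where the source analysis is silent, and what
the test suite does and does not establish.

## Partitioned survival model

Three mutually exclusive states — progression-free (PFS), progressed disease
(PD), dead — with occupancy read directly from two survival curves per
strategy: `pfs(t) = S_PFS(t)`, `dead(t) = 1 − S_OS(t)` and
`pd(t) = S_OS(t) − S_PFS(t)`.  No transition rates are modelled; the PSM is
exactly as identifiable as its two curves.  If the fitted curves cross
(`S_PFS > S_OS`, possible because the endpoints are fitted independently), PD
occupancy is clamped at zero and the number of clamped cycles is reported on
the trace and in the run manifest.

The cohort starts fully progression-free.  The horizon is the first cycle
boundary at which overall survival has fallen to 1 % **in both arms** (both
strategies must share a grid for incremental quantities to be well defined),
capped at 360 months.  Discounting is annual (base 5 %, deterministic range
0–8 %), compounded continuously in years from model start and applied to
costs, QALYs and — by convention, since the source discounts "all QALYs" and
prints life-years without comment — to life-years as well
(`CEAEvaluator(discount_rate=...)`; the trace exposes undiscounted time too).

### Time grids: `calendar` vs `reference`

The faithful grid (`calendar`) uses 21-day cycles of
21/(365.25/12) ≈ 0.6900 months, evaluates occupancy and discount weights at
cycle midpoints (equivalent to a half-cycle correction) and credits one cycle
of person-time per cycle.  Under this grid the base-case inputs give
discounted life expectancies of ~1.91 and ~1.43 years for the two overall-
population arms.

The published totals are substantially smaller (1.44 / 1.04 life-years) and
are **not** reachable from the published survival parameters under any plain
discount-rate/horizon variation of the calendar grid.  Reverse-engineering
the four printed life-year values shows they are all reproduced (within 0.04)
by a grid that advances the fitted survival curves and the discount weights
**one month per 3-week cycle** — i.e. the original spreadsheet used the cycle
index as the time argument of curves fitted on a months axis — while crediting
0.75 months (21 days at 28 days/month) of person-time per cycle, with
end-of-cycle evaluation and no half-cycle correction (the common spreadsheet
default).  This convention ships as `time_grid="reference"` and is used by the
packaged base-case configuration so that the published results can be
reproduced; `calendar` is the recommended default for new analyses.  This is
the single most consequential reconstruction decision in the package and the
main reason reported and recomputed totals agree.

Known residual discrepancies under the reference grid: the comparator arm of
the overall population carries a printed QALY (0.61) and implied incremental
cost (7,923.63 US$) that are inconsistent with that arm's own published
survival parameters — we obtain ≈ 0.68 QALYs and ≈ 6,475 US$ — while the
other three arms' life-years and QALYs and both ICERs reproduce closely
(overall ICER −5 %, subgroup ICER +0.3 %).  No parameter choice available to
this package moves only that arm; the discrepancy is reported, not patched.

## Survival machinery

Families and parameterizations (time in months):

| family | parameters | S(t) |
|---|---|---|
| exponential | rate λ | exp(−λt) |
| Weibull | shape a, scale b | exp(−(t/b)^a) |
| Gompertz | shape a, rate b | exp(−(b/a)(e^{at}−1)); defective tail allowed for a<0 |
| lognormal | μ, σ | 1 − Φ((ln t − μ)/σ) |
| log-logistic | μ, σ | 1/(1 + exp((ln t − μ)/σ)) |
| generalized gamma | μ, σ, Q | regularized incomplete gamma of Q⁻² e^{Q(ln t−μ)/σ} |

The published fitted parameters for the lognormal and log-logistic are read
as (μ, σ) of log-time in months: e^μ then equals the median, which matches the
trial's reported medians (e.g. e^2.8289 ≈ 16.9 months overall survival in the
combination arm), whereas a (shape, scale-in-months) reading would imply
sub-month medians.  The generalized gamma uses the (μ, σ, Q) form with
|Q| ≤ 5 (overflow guard); |Q| < 10⁻⁶ is evaluated as its lognormal limit, and
its log-density/log-survival are computed directly from `scipy.special`
incomplete-gamma functions for numerical stability at small |Q|.

Fitting maximizes the right-censored log likelihood
Σ_events ln f + Σ_censored ln S via multi-start L-BFGS-B (Nelder–Mead
fallback) on log-transformed positive parameters, started at
method-of-moments estimates of log-time plus four jittered restarts from a
fixed seed; the exponential rate uses its closed form events/time-at-risk.
AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ; `select_best` minimizes AIC, BIC or
their sum, breaking ties by fewer parameters and then by the canonical family
order.  The criterion-based choice is exposed separately from the shipped
base-case families, because the original selection also used (non-algorithmic)
visual inspection and in one arm (subgroup comparator overall survival) chose
the lognormal over a log-logistic with slightly better printed criteria.

### Pseudo-IPD reconstruction

Digitized curves (CSV: `time_months, survival[, n_risk]`) are first projected
onto non-increasing sequences by pool-adjacent-violators; an upward jump
larger than 0.02 is treated as corruption, not noise.  Reconstruction walks
the coordinates allocating the integer number of deaths that best reproduces
each Kaplan–Meier step given the current at-risk count; with a risk table the
surplus between at-risk counts becomes interval censoring spread uniformly,
without one no censoring is assumed before last follow-up.  The KM estimate
of the output matches the input coordinates within 1/(2·n_start) (exactly on
clean step inputs).  Fitting defaults to MLE on the reconstructed data;
least-squares directly on curve coordinates is provided as a secondary path.

## Costing

Per 3-week cycle, 2021 US$ (printed prices; the 6.4515 CNY/US$ rate is
metadata only).  Doses use the reference patient (65 kg, 1.64 m, BSA
1.72 m²): sintilimab 200 mg flat, cisplatin 75 mg/m², paclitaxel 175 mg/m²
(87.5 × 2 in cycle 1 — same milligrams), 5-FU 800 mg/m² × 5 days as the
alternative backbone, docetaxel 75 mg/m² for subsequent treatment.  Drugs are
priced linearly per mg from pack prices by default; whole-pack (wastage)
rounding is a flag because vial sizes beyond the sintilimab 100 mg vial are
not published.  The sintilimab price row is interpreted as 167.40 US$ per
**100 mg** vial: 167.40 × 6.4515 = 1,080 CNY, exactly the 2021 negotiated
price of the 100 mg vial, and the printed "1000 mg" pack is irreconcilable
with the published incremental cost (4× too small).

Accrual rules (frequencies are config keys; the source prints none of them):
first-line drug + administration (dispensing 4.01, IV 2.78, hospitalization
19.86/day × 1 day, 5 days for 5-FU) against PFS occupancy, treatment until
progression; follow-up 52.80 and labs 90.32 every cycle and chest+abdominal
CT (2 × 134.37) every 2 cycles against alive occupancy; BSC 117 per cycle
against PD occupancy (its wide deterministic range implies a recurring cost);
subsequent docetaxel + administration for at most 6 cycles per progressed
patient, approximated by the occupancy of "in PD, progressed within the last
6 cycles" = min(S_PFS(t−6c) − S_PFS(t), pd(t)), scaled by the arm's
subsequent-treatment share (41 % / 54 %); and a one-off incidence-weighted
serious-AE cost in cycle 1.  Grade 1–2 AEs carry a disutility but no cost,
mirroring the source.  QALYs: (pfs·0.741 + pd·0.581) × discounted person-time
per cycle, minus first-cycle disutilities (incidence × 0.01 for grade 1–2,
× 0.16 for grade 3–4, scaled by one cycle's person-time).

AE incidences are **not** published in the source table; the shipped
`ae_profile_synthetic.yaml` provides clearly-labelled constructed defaults
(plausible for this regimen class).  They enter only the one-off SAE cost and
first-cycle disutility, so their influence on incremental results is of order
tens of US$ and <0.01 QALY.

## Sensitivity analyses

One-way: each parameter to its low/high (printed range, else ±20 %; discount
0–8 %) with the full model re-run; the tornado metric is the ICER.  Entries
where the model degenerates (ΔQALY ≤ 0) are flagged, not dropped.

Probabilistic: all non-fixed parameters jointly sampled — beta for utilities,
disutilities and shares, gamma for prices and costs — with hyperparameters
moment-matched to mean = base and SD = (high − low)/(2·1.96) (the range is
read as a 95 % interval; for beta the SD is capped just below the feasibility
bound).  One master seed spawns a `SeedSequence` substream per parameter, so
adding a parameter never perturbs the others' draws.  Survival parameters and
the discount rate stay fixed in the PSA (no uncertainty is published for
them).  Because occupancy does not depend on sampled parameters, each
iteration only re-accumulates economics; 1,000 iterations run in ~1 s.  The
CEAC reports P(wtp·ΔQALY − ΔCost > 0); exact ties count as not
cost-effective.

## Synthetic data

`SimScenario` draws event times from a known truth by inverse-CDF sampling,
censors at min(administrative cutoff, exponential dropout) — non-informative
censoring, matching the assumption implicit in KM-based extrapolation — and
"digitizes" the KM estimate on a uniform grid with 3-decimal rounding (no
additive reading error) plus an exact risk table.  It does not simulate
accrual, informative dropout, digitizer noise, or patient-level cost
heterogeneity, so passing round-trip tests demonstrate correctness of the
pipeline under clean conditions, not robustness to messy real digitizations.
`gen_economic_fixture` jitters the base-case table (lognormal noise on costs,
logit noise on probabilities) while preserving all schema invariants.

## Numerical and testing notes

Occupancy conservation holds to 10⁻¹² per cycle by construction; exports are
rounded to 10 significant digits.  Parameter-recovery tests use n = 2000 with
~20 % censoring over 20 fixed seeds, judging each fit against 3 standard
errors from the finite-difference observed information; reconstruction
round-trips use n = 500 and 30 grid points; the shipped probabilistic
analysis uses the published 1,000 iterations.  These sizes keep the whole
suite around ten seconds while leaving Monte-Carlo margins well away from the
asserted bounds.

Known limitations: no spline or cure-fraction models, no interval censoring,
no covariate-adjusted survival; no EVPI or correlated PSA draws; subsequent
treatment is an occupancy-based approximation rather than an explicit tunnel
state; and the reference time grid intentionally reproduces a spreadsheet
convention rather than calendar time.
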