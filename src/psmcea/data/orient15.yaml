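# Base-case inputs of the ORIENT-15 cost-effectiveness analysis
# (first-line sintilimab + cisplatin/paclitaxel vs chemotherapy alone in
# advanced esophageal squamous cell carcinoma, Chinese healthcare system,
# 2021 US$ at 6.4515 CNY/US$ -- exchange rate is metadata only, no conversion
# is performed).
label: orient15
wtp_per_qaly: 37654.50        # 3 x 2021 per-capita GDP of 12,551.50 US$
per_capita_gdp: 12551.50
exchange_rate_cny_per_usd: 6.4515

settings:
  cycle_length_days: 21
  discount_rate: 0.05
  stop_quantile: 0.99
  # "reference" reproduces the published totals (the original spreadsheet
  # advanced the fitted survival curves one month per 3-week cycle and
  # credited 0.75 months of person-time per cycle); "calendar" is the
  # faithful 21-day grid.  See docs/methods.md.
  time_grid: reference
  max_horizon_months: 360

# Best-fitting distribution and (location, scale) of log-time per arm/endpoint,
# time in months.  location = log median for both families.
survival:
  overall:
    sintilimab_chemo:
      os:  {family: loglogistic, location: 2.828918, scale: 0.5166103}
      pfs: {family: lognormal,   location: 2.1923,   scale: 0.8939621}
    chemo:
      os:  {family: loglogistic, location: 2.512269, scale: 0.513398}
      pfs: {family: lognormal,   location: 1.733157, scale: 0.7921379}
  cps_ge_10:
    sintilimab_chemo:
      os:  {family: loglogistic, location: 2.862995, scale: 0.4700579}
      pfs: {family: lognormal,   location: 2.270911, scale: 0.9233276}
    chemo:
      os:  {family: lognormal,   location: 2.583066, scale: 0.8959587}
      pfs: {family: loglogistic, location: 1.800978, scale: 0.4471674}

economics:
  drug_prices:
    # The source table prints "Sintilimab/1000 mg"; 167.40 US$ x 6.4515 CNY/US$
    # is exactly the 1,080 CNY national-insurance negotiated price of one
    # 100 mg vial, so the pack size is taken as 100 mg.
    sintilimab:   {price: {value: 167.40, low: 133.92, high: 200.88, dist: gamma}, pack_mg: 100}
    cisplatin:    {price: {value: 11.78,  low: 9.42,   high: 14.14,  dist: gamma}, pack_mg: 50}
    paclitaxel:   {price: {value: 11.44,  low: 9.15,   high: 13.73,  dist: gamma}, pack_mg: 30}
    fluorouracil: {price: {value: 9.61,   low: 7.69,   high: 11.53,  dist: gamma}, pack_mg: 250}
    docetaxel:    {price: {value: 27.90,  low: 22.32,  high: 33.48,  dist: gamma}, pack_mg: 20}
  unit_costs:
    bsc_per_cycle: {value: 117,    low: 32.3,   high: 322.6,  dist: gamma}
    followup:      {value: 52.80,  low: 36.96,  high: 68.64,  dist: gamma}
    ct_chest:      {value: 134.37, low: 107.50, high: 161.24, dist: gamma}
    ct_abdomen:    {value: 134.37, low: 107.50, high: 161.24, dist: gamma}
    lab:           {value: 90.32,  low: 72.26,  high: 108.38, dist: gamma}
    dispensing_fee:          {value: 4.01,  dist: fixed}
    iv_fee:                  {value: 2.78,  dist: fixed}
    hospitalization_per_day: {value: 19.86, dist: fixed}
  sae_costs:
    anemia:                  {value: 669.45, low: 535.56,  high: 803.34, dist: gamma}
    wbc_decrease:            {value: 206.72, low: 165.376, high: 248.06, dist: gamma}
    neutrophil_decrease:     {value: 544.19, low: 435.35,  high: 613.43, dist: gamma}
    asthenia:                {value: 115.00, low: 92.00,   high: 138.00, dist: gamma}
    blood_pressure_increase: {value: 1.35,   low: 1.08,    high: 1.62,   dist: gamma}
  utilities:
    pfs: {value: 0.741, low: 0.593, high: 0.889, dist: beta}
    pd:  {value: 0.581, low: 0.465, high: 0.697, dist: beta}
  disutilities:
    g12: {value: 0.01, low: 0.008, high: 0.02,  dist: beta}
    g34: {value: 0.16, low: 0.11,  high: 0.204, dist: beta}
  subsequent_tx_share:
    sintilimab_chemo: {value: 0.41, dist: beta}
    chemo:            {value: 0.54, dist: beta}
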