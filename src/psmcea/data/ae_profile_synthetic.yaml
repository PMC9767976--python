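# SYNTHETIC adverse-event profile -- NOT authoritative.
#
# The cost-effectiveness source does not reprint per-event grade >=3 adverse
# event incidences or grade 1-2 incidences from the underlying trial.  The
# values below are plausible constructed defaults for first-line
# cisplatin + paclitaxel with or without a PD-1 inhibitor, in the ballpark of
# published trials of this class; replace them with trial-sourced numbers for
# any substantive re-analysis.  Their influence on the incremental results is
# small (a one-off first-cycle cost and disutility).
sae_incidence:
  sintilimab_chemo:
    anemia: 0.13
    wbc_decrease: 0.14
    neutrophil_decrease: 0.20
    asthenia: 0.02
    blood_pressure_increase: 0.03
  chemo:
    anemia: 0.11
    wbc_decrease: 0.13
    neutrophil_decrease: 0.18
    asthenia: 0.01
    blood_pressure_increase: 0.01
ae_incidence_g12:
  sintilimab_chemo: 0.95
  chemo: 0.93
ae_incidence_g34:
  sintilimab_chemo: 0.60
  chemo: 0.55
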