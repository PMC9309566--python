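# One-way deterministic sensitivity-analysis scenarios (tornado set).
# Each scenario re-runs both strategies with the parameter at its low and
# high bound.  Bounds come from the published uncertainty ranges where
# available; breast-cancer treatment costs for the untested group vary by
# +/-40% (mode: scale); the test-cost scenario varies the number of
# relatives tested per index case (4 relatives -> R$ 685 per woman,
# 1 relative -> R$ 2,035).
scenarios:
  - name: discount_rate
    path: model.discount_rate
    low: 0.0
    high: 0.10
  - name: bc_after_both_surgeries
    path: probabilities.post_surgery.bc_after_both
    low: 0.0
    high: 0.08
  - name: relatives_tested_per_index
    path: costs.n_relatives_per_index
    low: 4
    high: 1
  - name: oc_after_oophorectomy
    path: probabilities.post_surgery.oc_after_oophorectomy
    low: 0.004
    high: 0.03
  - name: bc_treatment_cost_untested
    path: costs.bc_index_yearly
    mode: scale
    low: 0.6
    high: 1.4
  - name: bc_after_oophorectomy_30_34
    path: probabilities.post_surgery.bc_after_oophorectomy.bands.0.p
    low: 0.010
    high: 0.018
  - name: recurrence_bc_carrier
    path: probabilities.recurrence_bc_carrier
    low: 0.054
    high: 0.091
  - name: bc_to_metastatic
    path: probabilities.bc_to_metastatic
    low: 0.0097
    high: 0.01737
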