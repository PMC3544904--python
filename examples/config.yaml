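# Example end-to-end configuration for `cnvpanel run-all`.
# Simulates a 200-sample cohort over three targeted CNV regions and runs
# both callers, consensus, QC, association and selection.
seed: 7
out_dir: demo_out
design:
  n_cases: 60
  n_controls: 140
  batch_count: 2
  noise_sd_lrr: 0.15
  rng_seed: 7
region_specs:
  - {region_id: nrxn1_like, chromosome: '2', start_bp: 51000000, end_bp: 51070000,
     cnv_type: loss, case_carrier_freq: 0.10, control_carrier_freq: 0.03}
  - {region_id: dup_15q, chromosome: '15', start_bp: 31000000, end_bp: 31050000,
     cnv_type: gain, case_carrier_freq: 0.12, control_carrier_freq: 0.04}
  - {region_id: xq_del, chromosome: X, start_bp: 140000000, end_bp: 140050000,
     cnv_type: loss, case_carrier_freq: 0.08, control_carrier_freq: 0.02}
selection:
  min_odds_ratio: 2.0
  min_case_carriers: 2
  max_validation_samples: 6
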