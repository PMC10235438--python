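# Two-cohort demonstration: control vs shifted-excitability neurons.
cohorts:
  control:
    n_cells: 8
    cell_jitter_sd: 0.08
  shifted:
    n_cells: 8
    cell_jitter_sd: 0.08
    na_shift: -1.5
    g_adapt: 12.0
protocol:
  levels_start: 0.0
  levels_stop: 100.0
  levels_step: 10.0
analysis:
  dvdt_threshold: 20.0
  min_aps: 6
  junction_potential: 10.0
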