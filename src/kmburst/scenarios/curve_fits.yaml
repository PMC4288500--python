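# Curve-fitting round trips against the reported parameter values:
# Hill EC50 (9.8 uM) from a seeded 200-cell dose-response table, Boltzmann
# activation (control -26.8 mV / 1.86 e, drug-shifted -44.3 mV / 2.01 e),
# whole-cell slope (2.11 nS), BK single-channel conductance (180 pS),
# single-channel Po (0.211) and action-current frequency (1.21 Hz).
name: curve_fits
seed: 1
stages:
  - {kind: dose_response, id: dose, hill: {e_max: 100.0, ec50: 9.8, n_h: 1.0},
     concentrations: [0.1, 1, 3, 10, 30, 100, 300], n_cells: 200}
  - {kind: fit_hill, id: hill_fit, input: dose}
  - {kind: ikm_sweeps, id: sweeps_ctrl,
     boltzmann: {g_max: 2.11, v_half: -26.8, q: 1.86},
     trace_noise_sd: 0.0, cell_cv: 0.0, n_cells: 1}
  - {kind: fit_boltzmann, id: boltz_ctrl, input: sweeps_ctrl}
  - {kind: ikm_sweeps, id: sweeps_ngen,
     boltzmann: {g_max: 2.11, v_half: -44.3, q: 2.01},
     trace_noise_sd: 0.0, cell_cv: 0.0, n_cells: 1}
  - {kind: fit_boltzmann, id: boltz_ngen, input: sweeps_ngen}
  - {kind: iv_table, id: slope_iv, conductance_pS: 2110.0, reversal_mV: -91.0,
     potentials_mV: [-30, -20, -10]}
  - {kind: conductance_slope, id: slope_ngen, input: slope_iv,
     window: [-30.0, -10.0]}
  - {kind: iv_table, id: bk_iv, conductance_pS: 180.0, reversal_mV: 0.0,
     potentials_mV: [-60, -40, -20, 0, 20, 40, 60]}
  - {kind: single_channel_conductance, id: bk_scc, input: bk_iv, reversal_mV: 0.0}
  - {kind: single_channel, id: bk_trace, seed: 7,
     spec: {n_channels: 1, open_probability: 0.211, unitary_amplitude_pA: 10.8,
            mean_open_time_ms: 2.0, duration_ms: 60000.0}}
  - {kind: npo, id: bk_po, input: bk_trace}
  - {kind: action_train, id: train, seed: 3, rate_hz: 1.21, duration_s: 100.0}
  - {kind: detect_events, id: firing, input: train}
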