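# Fast-slow analysis: saddle-node (voltage-nullcline) boundaries on the
# n-o plane and projected burst loops for the three conductance settings.
name: fast_slow
seed: 42
stages:
  - {kind: simulate, id: traj_base,  modulation: {g_M_scale: 1.0, g_KCa_scale: 1.0},
     duration_ms: 7000.0, dt_ms: 0.002, write_trace: false}
  - {kind: simulate, id: traj_gm2,   modulation: {g_M_scale: 2.0, g_KCa_scale: 1.0},
     duration_ms: 7000.0, dt_ms: 0.002, write_trace: false}
  - {kind: simulate, id: traj_both2, modulation: {g_M_scale: 2.0, g_KCa_scale: 2.0},
     duration_ms: 7000.0, dt_ms: 0.002, write_trace: false}
  - {kind: nullcline, id: null_base,  modulation: {g_M_scale: 1.0, g_KCa_scale: 1.0},
     ca_from: traj_base, n_points: 21}
  - {kind: nullcline, id: null_gm2,   modulation: {g_M_scale: 2.0, g_KCa_scale: 1.0},
     ca_from: traj_base, n_points: 21}
  - {kind: nullcline, id: null_both2, modulation: {g_M_scale: 2.0, g_KCa_scale: 2.0},
     ca_from: traj_base, n_points: 21}
  - {kind: project_trajectory, id: loop_base,  input: traj_base,  transient_ms: 1500.0}
  - {kind: project_trajectory, id: loop_gm2,   input: traj_gm2,   transient_ms: 1500.0}
  - {kind: project_trajectory, id: loop_both2, input: traj_both2, transient_ms: 1500.0}
  - {kind: nullcline_shift, id: shift_gm2,   a: null_base, b: null_gm2}
  - {kind: nullcline_shift, id: shift_both2, a: null_base, b: null_both2}
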