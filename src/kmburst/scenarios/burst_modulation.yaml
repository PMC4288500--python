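# Burst-firing scenarios: baseline conductances, g_M doubled, and both
# g_M and g_KCa doubled (the pharmacological-activation surrogate).
name: burst_modulation
seed: 42
stages:
  - {kind: simulate, id: mod_base,  modulation: {g_M_scale: 1.0, g_KCa_scale: 1.0},
     duration_ms: 3000.0, dt_ms: 0.001}
  - {kind: simulate, id: mod_gm2,   modulation: {g_M_scale: 2.0, g_KCa_scale: 1.0},
     duration_ms: 3000.0, dt_ms: 0.001}
  - {kind: simulate, id: mod_both2, modulation: {g_M_scale: 2.0, g_KCa_scale: 2.0},
     duration_ms: 3000.0, dt_ms: 0.001}
  - {kind: burst_metrics, id: metrics_base,  input: mod_base}
  - {kind: burst_metrics, id: metrics_gm2,   input: mod_gm2}
  - {kind: burst_metrics, id: metrics_both2, input: mod_both2}
  - {kind: fold_change, id: im_fold, a: mod_base, b: mod_both2, current: I_M}
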