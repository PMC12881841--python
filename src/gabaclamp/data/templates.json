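{
  "description": "Default simulated GABA-A conductance library: 4 amplitudes x 2 decay time constants, reversal potential -36.5 mV, sampled at 0.1 ms.",
  "e_rev_mV": -36.5,
  "dt_ms": 0.1,
  "duration_ms": 100.0,
  "templates": [
    {"id": "g1_tau7",   "g_max_nS": 1.0,  "tau_ms": 7.0},
    {"id": "g2_tau7",   "g_max_nS": 2.0,  "tau_ms": 7.0},
    {"id": "g5_tau7",   "g_max_nS": 5.0,  "tau_ms": 7.0},
    {"id": "g10_tau7",  "g_max_nS": 10.0, "tau_ms": 7.0},
    {"id": "g1_tau10",  "g_max_nS": 1.0,  "tau_ms": 10.0},
    {"id": "g2_tau10",  "g_max_nS": 2.0,  "tau_ms": 10.0},
    {"id": "g5_tau10",  "g_max_nS": 5.0,  "tau_ms": 10.0},
    {"id": "g10_tau10", "g_max_nS": 10.0, "tau_ms": 10.0}
  ]
}
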