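{
  "params": {
    "a": 15.0,
    "r_k": 0.3,
    "r_c": 1.2,
    "n_c": 46,
    "v_g": 12.0,
    "v_s": 14.0,
    "f_g": 6.0,
    "f_s": 4.0,
    "p_cat0": 0.058,
    "f_cat": 2.4,
    "p_res0": 0.045,
    "f_res": 2.3,
    "n_mt": 10000,
    "k_nucl": null,
    "p_sc": 0.1,
    "scaffold_overlap": 0.6,
    "tau_mt": 60.0,
    "f_pef": 0.5,
    "f_cenpe": 50.0,
    "f_dyn": 50.0,
    "n_k": 25,
    "k_k": 100.0,
    "p_detach_u0": 0.1,
    "f_detach_u": 4.0,
    "p_detach_s0": 0.001,
    "f_detach_s": 4.0,
    "delta_pole": 3.0,
    "attach_refractory": 5.0,
    "eta_pn_s_per_um": 1000.0,
    "dt": 0.1,
    "interaction_every": 5,
    "warmup": 300.0,
    "boundary_processive": true,
    "congression_eps": 0.1,
    "pef_geometry": "disk"
  },
  "scenario": "wt_scattered",
  "seed": 0,
  "congression_deadline": 1000.0,
  "biorientation_deadline": 100000.0,
  "snapshot_every": 1.0,
  "record_events": false,
  "record_trajectory": false,
  "trajectory_every": 10.0
}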