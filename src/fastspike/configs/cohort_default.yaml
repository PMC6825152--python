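# Default generative profile for synthetic current-clamp cohorts.
#
# Each cell starts from one of the shipped base configurations, jitters
# its densities and passive parameters (log-normal, sd = jitter_sd in
# log space), and draws a nominal Kv3.1 density from its class range:
# regular-spiking cells stay in the low range spanned by published
# detailed models; fast-spiking cells sit at the high densities that
# produce narrow spikes, large fAHP and little accommodation.
classes:
  rs:
    base_models: [rs_a, rs_b, rs_c, rs_d]
    kv31_range: [0.05, 0.6]
    jitter_sd: 0.05
    jitter_fields: [na_t, kdr_t, km, g_leak, area]
  fs:
    base_models: [rs_b]
    kv31_range: [1.4, 1.9]
    jitter_sd: 0.05
    jitter_fields: [na_t, kdr_t, km, g_leak, area]
protocol:
  dt: 0.05
  onset: 100.0
  step_duration: 800.0
  tail: 100.0
  settle: 300.0
  subthreshold_currents: [-50, -40, -30, -20, -10, 0, 10, 20]
  depolarizing_currents: {start: 25, stop: 500, step: 25}
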