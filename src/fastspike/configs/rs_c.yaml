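# Regular-spiking configuration "C": stronger accommodation (more M-type
# conductance), slightly leakier and smaller membrane.
name: rs_c
cm: 1.0
area: 1.9e-5
g_leak: 1.1e-4
e_leak: -65.0
v_init: -70.0
channels:
  na_t: 0.10
  kdr_t: 0.0012
  km: 0.0012
  kv31: 0.29
channel_scale:
  kv31: 0.10
phi:
  na_t: [1.0, 0.7]
  kdr_t: [0.7]
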