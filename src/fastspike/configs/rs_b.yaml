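# Regular-spiking configuration "B": near-zero baseline Kv3.1, stronger
# delayed rectifier and sodium densities.
name: rs_b
cm: 1.0
area: 2.0e-5
g_leak: 1.0e-4
e_leak: -65.0
v_init: -70.0
channels:
  na_t: 0.12
  kdr_t: 0.0040
  km: 0.0010
  kv31: 0.009
channel_scale:
  kv31: 0.15
phi:
  na_t: [1.0, 0.7]
  kdr_t: [0.7]
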