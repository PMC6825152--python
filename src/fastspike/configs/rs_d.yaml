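# Regular-spiking configuration "D": highest baseline Kv3.1 of the four,
# larger membrane, lower leak.
name: rs_d
cm: 1.0
area: 2.1e-5
g_leak: 0.9e-4
e_leak: -65.0
v_init: -70.0
channels:
  na_t: 0.11
  kdr_t: 0.0015
  km: 0.0010
  kv31: 0.56
channel_scale:
  kv31: 0.03
phi:
  na_t: [1.0, 0.7]
  kdr_t: [0.7]
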