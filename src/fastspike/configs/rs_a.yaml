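# Regular-spiking single-compartment configuration "A".
# Nominal Kv3.1 density is on the somatic scale of morphologically
# detailed models; channel_scale.kv31 is the somatic area fraction of
# the reduced geometry.  phi entries slow selected gates (per-gate rate
# multipliers) to the effective recording temperature.
name: rs_a
cm: 1.0
area: 2.0e-5
g_leak: 1.0e-4
e_leak: -65.0
v_init: -70.0
channels:
  na_t: 0.10
  kdr_t: 0.0010
  km: 0.0010
  kv31: 0.25
channel_scale:
  kv31: 0.06
phi:
  na_t: [1.0, 0.7]
  kdr_t: [0.7]
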