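# Three-region "attention to visual motion" network, forward variant.
#
# V1 and V5 are bidirectionally connected, as are V5 and SPC; the driving
# Photic input enters V1, and both modulations (Motion, Attention) act on the
# forward connection V1 -> V5.  7 A-parameters + 2 B + 1 C = 10 free
# parameters.
#
# The parameter values are documented plausible choices, NOT estimates from
# any real dataset: inhibitory self-connections of -0.8 Hz (strong enough
# that the system stays stable even when both modulations raise V1 -> V5 to
# 1.1 Hz), modest positive inter-regional couplings, and conventional driving
# and modulatory gains.
#
# The stimulus trains are rule-generated alternating epochs: 32.2 s blocks
# with 64.4 s onset spacing for the driving input; Motion on every second
# Photic block and Attention on every fourth (attention blocks are a subset
# of motion blocks, as in blocked attention-to-motion paradigms).
name: forward
regions: [V1, V5, SPC]
inputs: [Photic, Motion, Attention]
a:
  mask:
    - [1, 1, 0]
    - [1, 1, 1]
    - [0, 1, 1]
  values:
    - [-0.8, 0.3, 0.0]
    - [0.3, -0.8, 0.3]
    - [0.0, 0.3, -0.8]
b:
  - input: Motion
    mask:
      - [0, 0, 0]
      - [1, 0, 0]
      - [0, 0, 0]
    values:
      - [0.0, 0.0, 0.0]
      - [0.4, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
  - input: Attention
    mask:
      - [0, 0, 0]
      - [1, 0, 0]
      - [0, 0, 0]
    values:
      - [0.0, 0.0, 0.0]
      - [0.4, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
c:
  mask:
    - [1, 0, 0]
    - [0, 0, 0]
    - [0, 0, 0]
  values:
    - [0.8, 0.0, 0.0]
    - [0.0, 0.0, 0.0]
    - [0.0, 0.0, 0.0]
design:
  tr: 3.22
  n_slices: 32
  n_volumes: 360
  stimuli:
    Photic: {start: 0.0, spacing: 64.4, duration: 32.2, count: 18}
    Motion: {start: 64.4, spacing: 128.8, duration: 32.2, count: 9}
    Attention: {start: 193.2, spacing: 257.6, duration: 32.2, count: 4}
snr: 10
seed: 0
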