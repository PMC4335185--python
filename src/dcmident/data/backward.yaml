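# Three-region "attention to visual motion" network, backward variant.
#
# Same A and C structure and values as the forward variant, but the two
# modulations sit on one forward and one backward connection: Motion on
# V1 -> V5 and Attention on SPC -> V5.  Which modulation sits on which
# connection is a configurable convention (this assignment follows the
# standard backward variant of the paradigm).
name: backward
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
      - [0, 0, 1]
      - [0, 0, 0]
    values:
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.4]
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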