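# Configuration schema

Model + design configurations are plain structured text (YAML; JSON works
unchanged, being a YAML subset).  Top-level keys:

| key       | required | meaning |
|-----------|----------|---------|
| `regions` | yes      | list of region labels, length `m` |
| `inputs`  | yes (may be empty) | list of input labels, length `n` |
| `a`       | yes      | `{mask, values}`: `m×m` fixed-connection matrix A (Hz) |
| `b`       | no       | list of `{input, mask, values}` blocks, one per modulatory input; omitted inputs have zero B |
| `c`       | yes      | `{mask, values}`: `m×n` driving-input matrix C |
| `design`  | yes      | acquisition + stimulus timing (below) |
| `snr`     | no       | signal-to-noise ratio as SD(signal)/SD(noise); default 10 |
| `seed`    | no       | RNG seed for noise; default 0 |

Masks are binary (0/1); `values` must be zero wherever the mask is zero and
may be omitted (then all zeros).  The diagonal of `a.mask` must be all ones:
self-connections are always part of the model.

## `design`

| key         | meaning |
|-------------|---------|
| `tr`        | repetition time in seconds |
| `n_slices`  | slices per volume; the ODE microtime step is `tr / n_slices` |
| `n_volumes` | volumes acquired; session length is `tr * n_volumes` |
| `stimuli`   | mapping from input label to a stimulus train |

A stimulus train is either an explicit list of `[onset_s, duration_s]` or
`[onset_s, duration_s, amplitude]` entries, or a generating rule

```yaml
stimuli:
  Photic: {start: 0.0, spacing: 64.4, duration: 32.2, count: 18}
  Motion: [[64.4, 32.2], [193.2, 32.2]]
```

which expands to `count` boxcars at `start + k * spacing`.  Boxcars are
active on the half-open interval `[onset, onset + duration)`; overlapping
boxcars of the same input add their amplitudes.  All onsets must be ≥ 0 and
`onset + duration ≤ tr * n_volumes`.

The bundled fixtures (`src/dcmident/data/forward.yaml`,
`.../backward.yaml`) are complete examples.
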