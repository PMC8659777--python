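# Methods note

## Signal model and assumptions

During walking, the arm swing moves and rotates a wrist-worn magnetometer
through the Earth's field, so one measured field component oscillates
approximately sinusoidally at the stride frequency

```
f [Hz] = (walk_speed [km/h] / 3.6) / stride_length [m]
```

with **two steps per stride period** — one at each extremum of the swing.
For 4–6.5 km/h at a 1.3 m stride this gives f ∈ [0.85, 1.39] Hz; the step
rate is 2f ∈ [1.71, 2.78] Hz. The simulator generates

```
B(t) = field_mean + ΔB · sin(2π f t + φ) + noise + disturbances
```

per walking segment, with ground-truth step times at the analytic extrema
of the sinusoid. Standing segments contribute only the constant field plus
noise. An optional `double_frequency_fraction` adds a 2f harmonic (some
wrist motions produce a doubled oscillation); when it is non-zero the
ground truth falls back to a numeric extrema scan of the noise-free
waveform.

What the simulator **does** emulate: sensor noise (white Gaussian, default
σ = 0.25 µT, matching a typical low-cost magnetometer datasheet),
16-bit quantisation at 0.1 µT/LSB over ±1000 µT, segment sequences
(walk/stand), and localised magnetic disturbances as Gaussian pulses.

What it **does not** emulate: coloured or impulsive interference, gradual
speed changes (segment transitions are instantaneous), arm gesticulation
unrelated to gait, soft/hard-iron effects, or orientation drift. The
single-sinusoid swing model is an idealisation; real wrist traces are
periodic but not sinusoidal.

## Processing chain and parameters

| Parameter | Default | Why |
|---|---|---|
| Sampling rate | 40 Hz | Typical magnetometer output data rate; ≥ 14× the highest step rate. |
| Block size | 80 samples (2 s) | Streaming granularity; must exceed the filter order so one historical block fully warms up the filter. |
| FIR order | 47 (48 taps) | Hamming-windowed sinc; > 40 dB stopband attenuation at 4 Hz with a transition band that leaves the 0.85–1.39 Hz gait band untouched. |
| Cutoff | 2 Hz | Above the highest stride frequency (1.39 Hz), below noise/interference. |
| Fake-step threshold | 0.5 µT | Minimum peak-to-valley amplitude of a genuine arm swing; well above residual filtered noise. |
| Motionless threshold | 0.6 µT | 3 × the expected raw-sample mean absolute deviation of standing noise, σ√(2/π) ≈ 0.199 µT at σ = 0.25 µT. `calibrate_motionless_threshold` recomputes it from recorded standing traces. |
| Field mean / swing | 48 µT / 5 µT | Mid-latitude field magnitude; observed wrist-swing modulation depth. |

**Buffering.** Samples stream into a three-subblock circular buffer
(historical / current / pending). When the pending subblock fills, roles
rotate; samples arriving mid-processing are staged in an overflow queue,
so no sample is ever dropped (property-tested).

**Filtering.** Each block is filtered with the previous block as start-up
context, making block-wise output bit-identical to single-pass
convolution (tested to < 1e-12). The filter is linear-phase with group
delay `order/2 = 23.5` samples (0.59 s); all reported step times are
corrected by this constant.

**Detection.** Extrema are found by neighbour comparison; plateaus are
run-compressed and represented by their first sample. The threshold
filter walks the alternating peak/valley sequence: a candidate opposite
in kind to the last accepted extremum is accepted if the amplitude gap
reaches the threshold; otherwise both the candidate **and the following
same-kind extremum** are skipped. Blocks whose filtered mean absolute
deviation falls below the motionless threshold are labelled motionless
and their extrema discarded (applied last, so a quiet block interrupts
counting without corrupting the alternation logic). Each surviving
extremum is one step.

## Numerical choices at the record boundaries

A finite recording differs from the endless stream the method was designed
for in two places:

- **Head.** The first block has no history. Zero-padding would inject a
  ~48 µT DC step whose transient registers as a step on standing-only
  input, so the first block is warmed up by edge replication (steady
  state at the signal's own level), and the first ⌊23.5⌋ = 23 filtered
  samples — which encode padding, not measurement — are excluded from
  extrema detection.
- **Tail.** An extremum within one group delay of the end needs future
  samples. The raw signal is extended by a local quadratic fit to its
  last 8 samples (a short-horizon Taylor continuation preserving level,
  slope and curvature), which recovers apexes down to ~1 sample inside
  the record without creating spurious ones. Motion labels are computed
  only on the pad-free filtered samples, so extrapolation of pure noise
  cannot mark a standing block as moving.

## Evaluation

Accuracy is the symmetric ratio `100 · min(detected, true) / max(detected,
true)`, rounded to one decimal; it penalises over- and under-counting
equally and is scale-invariant (property-tested). The benchmark harness
(`run_benchmark`) scores the pipeline over simulated scenarios and, with
multiple trials, reports the worst trial per scenario.

## Known limitations

- **The threshold rule is not monotone in its threshold.** Because
  rejecting a candidate also skips the next same-kind extremum, a larger
  threshold can reroute the scan onto a path accepting *more* extrema.
  Minimal counterexample (frozen in the tests): extrema values
  (P4, V2, P3, V0, P3) yield 2 accepted at threshold 1.5 but 3 at 2.5.
  On actual gait traces the end-to-end step count is non-increasing in
  the threshold (tested across threshold sweeps); the pathology requires
  adversarial amplitude patterns.
- **±1 step at the record end.** An extremum whose apex lies within about
  one sample of the final sample may still be missed despite the
  quadratic tail extension; no symmetric-FIR scheme can resolve it
  without genuine future data.
- **No gesticulation rejection.** Arm movements with gait-like amplitude
  and frequency are counted as steps; the motionless filter only removes
  quiet periods.
- Traces shorter than one block (2 s) produce a warning and a zero-step
  report rather than a partial estimate.

All quantitative claims above (filter attenuation, boundary behaviour,
accuracy figures) are computed by the test suite and
`scripts/acceptance.py`, not asserted from external sources.
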