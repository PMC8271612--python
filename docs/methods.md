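# Methods

## Model and pipeline

The package estimates respiratory rate (RR) from a time-ordered stack of
single-channel thermal frames with a known sampling rate and a face
bounding box (static, or one per frame from any pluggable detector). The
processing chain per analysis window is:

1. split the face box into a 4×6 grid (4 columns × 6 rows; a face is about
   twice as tall as wide, so cells are roughly square);
2. per cell, take the mean pixel intensity per frame in double precision
   from the raw integer counts — no 8-bit conversion on the signal path;
3. slice a 15 s rectangular window (plain truncation, no taper: frequency
   resolution matters more than sidelobe level for a narrowband tone) and
   remove the least-squares affine trend;
4. periodogram `P(f) = |DFT|²/(N·fs)` on a zero-padded grid; the spectral
   peak in the breath band [0.1, 2.0] Hz gives `RRf = 60·f_peak` bpm;
5. zero crossings of the detrended window give interval frequencies whose
   median is `RRt`;
6. spectral-shape fractions `F_BF`, `F_HF`, the Spectrum Index
   `SI = 1 − (F_BF + F_HF)/2`, and the Respiratory Quality Index
   `RQI = SI · G(a − |RRt − RRf|)`;
7. the max-RQI cell's `RRf` is the reported rate. If every cell is
   degenerate (zero spectrum, or quality 0) the window reports "no
   respiratory region found" rather than a number.

Assumptions: the subject is roughly still (per-frame boxes absorb detector
jitter, not head rotation); breathing produces a quasi-periodic intensity
oscillation somewhere inside the face box; the sampling rate is trusted
user metadata (no container metadata is read).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| window length | 15 | s | time/frequency-resolution trade-off |
| fps | 8.6 | frames/s | reference thermal-camera rate; any positive value works |
| breath band | 0.1–2.0 | Hz | estimable RR range 6–120 bpm; BF closed, HF half-open above 2 Hz |
| `n_fft` | 8192 | — | zero-padded grid ≈ 0.063 bpm at 8.6 fps (native grid of a 15 s window is 4 bpm, too coarse for sub-bpm readout) |
| `a` | 5 | bpm | logistic shift: cross-domain disagreements ≪ 5 bpm keep their SI |
| BF / HF thresholds | 0.25 / 0.10 | of `P_BFMAX` | indicator cutoffs in `F_BF` / `F_HF`; comparisons use ≥ so threshold-exact bins count |
| grid | 4 × 6 | cols × rows | a 6 × 4 transpose is available for sensitivity checks |

## Numerical choices

* **Periodogram scaling.** `N` in `1/(N·fs)` is the unpadded sample count;
  zero padding refines the grid without rescaling the estimate. No
  one-sided doubling is applied — all consumers (peak location, ratios of
  in-band sums) are invariant to it, and the values then match the
  two-sided definition bin for bin.
* **Band membership.** BF is the closed interval [0.1, 2.0] Hz; the bin at
  exactly 2.0 Hz belongs to BF. The HF integral's upper limit is truncated
  at Nyquist, unavoidable for sampled data.
* **Zero-crossing convention.** A one-directional (positive-to-negative)
  crossing count spaces crossings one full period apart, so a factor
  `2/Δ` would read twice the true frequency. The default therefore detects
  *both* sign changes (half-period spacings) and uses `f = 1/(2Δ)`, which
  recovers the tone and makes `RRt ≈ RRf` on clean signals — the agreement
  the quality gate is built on. A `"literal"` mode (one-directional,
  `f = 2/Δ`) is kept for comparison. Crossing times are linearly
  interpolated between bracketing samples; exact-zero samples belong to the
  following sign, so touching zero without crossing does not count.
* **Degenerate rules.** All-zero breath band → both fractions set to 1
  (maximally noise-like), region flagged; zero total HF power with a live
  breath band → `F_HF = 0`; fewer than two crossings → `RRt` undefined and
  RQI forced to 0. Argmax ties (spectral peak, region selection) break to
  the lowest frequency / region index for reproducibility. The median of
  an even number of interval frequencies is the mean of the central pair.
* **Detrending** is a single affine fit (mean removal subsumed); it is
  idempotent and applied before every spectral or crossing computation.

## Synthetic scenes

The simulator emulates the validation setting the method targets: a
face-sized box in which a subset of grid cells ("nose-level" cells 9–10 by
default) carries `baseline + drift·t + A(sin 2πft + d·sin 4πft) + noise`,
all other cells drift + noise only, quantized to uint16 with clipping
accounted. Defaults: 64×64 frames, 40×60 face box, baseline 30 000 counts,
amplitude 60 counts, per-pixel Gaussian noise σ = 15 (per-pixel SNR
`A²/2σ²` ≈ 9 dB; cell averaging over ~100 pixels raises the trace-level
SNR by ~20 dB), per-cell drift slope uniform in ±2 counts/s, second
harmonic fraction 0.2 (breathing is not a pure sinusoid), 15 s at 8.6 fps.
The amplitude scale is chosen to exercise the algorithm, not to mimic any
specific radiometric calibration. Benchmarks sweep rates 15/20/25/30 bpm —
rates a cooperative subject can hold — with per-scene seeds spawned from a
master seed.

What the simulator does **not** model: head motion and rigid shake,
anatomical temperature texture, detector misses, occlusions (masks, hair
across the nose), and airflow turbulence. Passing the recovery suite shows
the signal chain and selection logic are correct under the stated noise
model; it does not certify performance on real patients.

## Observed behaviour worth knowing

* Because `F_BF` and `F_HF` are *power-weighted*, a clean tone has
  `F_BF ≈ 1` (the peak lobe carries nearly all band power) and SI ≈ 0.5;
  moderate broadband noise adds sub-threshold power to the BF denominator
  and can transiently *raise* SI before the flattening spectrum pulls it
  down. SI alone is therefore not monotone in noise; the combined RQI is,
  because the cross-domain agreement gate collapses under the same noise.
  Region selection relies on the combination, not on SI alone.
* Rectangular-window leakage from a partial last cycle biases the
  fine-grid spectral peak by a few padded bins (~0.1–0.2 bpm); accuracy is
  native-bin, and zero padding is for readout smoothness, not resolution.

## Limitations

Single-subject scenes only; no apnea detection (a rate of 0 is outside the
estimable 6–120 bpm range by construction); no motion compensation; no
learned combination of the quality features; face detection itself is out
of scope — any box provider satisfying the `DetectorProvider` contract can
be plugged in.
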