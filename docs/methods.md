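# Methods

## Pipeline

`cisquant` quantifies cisplatin from the color-development kinetics of a
nanozyme/TMB assay filmed by a fixed camera. The pipeline is distance-based
classification onto the concentration grid of a reference (training) set:

1. each tube's (R, G, B) intensity trace is block-averaged (5 s window,
   5 s stride by default), which both denoises and shortens the series —
   150 samples at 1 Hz become 30;
2. dissimilarity between two tubes is dynamic time warping applied to each
   channel independently, averaged over channels;
3. the query receives the concentration label of its nearest reference tube
   (k = 1);
4. leave-one-out over a labeled dataset measures how well the grid levels
   can be told apart.

Prediction is assignment to a training label, not interpolation: the method
cannot output a concentration that is absent from the reference set, and
its natural failure mode is sliding to an *adjacent* grid level.

### DTW conventions

The step pattern is the basic symmetric one (insert, delete, diagonal, all
weight 1), the local cost is the absolute difference (squared cost
available), there is no path-length normalization, and no global band
constraint by default — with 30-sample series the full O(n·m) table is
cheap. An optional Sakoe–Chiba band (`window_constraint`, in samples) is
provided; it must be at least the length difference of the two series.
These conventions are declared package defaults: distance-based assignment
is robust to the exact choice, and all of them are configurable. DTW is
symmetric and non-negative with zero self-distance but is **not** a metric
(the triangle inequality can fail), and nothing in the package assumes it
is.

The all-pairs `distance_matrix` fills the DP tables of all equal-length
pairs in lockstep (vectorized over pairs); it is tested to agree exactly
with the scalar reference implementation, which in turn is tested against
an exhaustive warping-path enumeration oracle on short sequences.

### Tie-breaking and determinism

Equal distances are resolved toward the lower concentration (conservative
for contamination screening), then by tube id; predictions are therefore
invariant to the ordering of the input dataset. Preprocessing is
per-series, so applying it once up front is identical to applying it inside
every leave-one-out fold.

## Synthetic data model

No recordings of the assay are public, so the generator emulates the study
design directly. Its physical skeleton:

* **Amplitude** saturates in catalyst amount:
  `A∞(c) = Amax · c / (c + c½)`. Defaults `Amax = 1`, `c½ = 150` (in the
  unit-agnostic concentration units of the design grid, nominally ppb).
* **Kinetics** are first-order in time with a concentration-coupled rate,
  `A(c,t) = A∞(c) · (1 − e^(−k(c) t)`, `k(c) = k₀ (c/c_ref)^γ`, defaults
  `k₀ = 0.035 s⁻¹` at `c_ref = 1200`, `γ = 0.3`. High-concentration tubes
  approach full color within minutes, consistent with fast visual color
  development; low-concentration tubes are still rising at 150 s, so curve
  *shape* as well as level carries concentration information.
* **Optics**: Beer–Lambert attenuation of the baseline,
  `I_ch = I⁰_ch · 10^(−ε_ch A)`, with ε ordered red ≥ green ≥ blue
  (defaults 1.2, 0.45, 0.08) because oxidized TMB is blue and absorbs red;
  baseline (0.92, 0.90, 0.88) is a transparent tube under white light.
* **Noise**: one lognormal amplitude multiplier per tube (mean 1, CV
  `replicate_amplitude_cv`, default 0.003) modelling pipetting/catalyst
  variability, plus i.i.d. Gaussian camera noise per sample and channel
  (`noise_sd`, default 0.004 ≈ 1 gray level of an 8-bit camera). Intensities
  are clipped to [0, 1]. Lighting drift is off by default (`drift_per_s`),
  matching a fixed-lighting protocol.

The default `DatasetDesign` encodes the 62-tube study: the 22 low-range
tubes are split 3 per level across {1.5, 3, 6.5, 17, 33, 45, 65} with one
extra tube at 33 (the exact split below 22 tubes is not fixed by the study
description; this choice is configurable), and 4 replicates at each of the
10 high levels.

### Noise calibration

The noise defaults are part of the study conditions: they were calibrated
(once, via a several-hundred-dataset study) so that the generator
reproduces the qualitative error regime reported for the real assay —
noise-free data give 100% exact leave-one-out recovery; under default noise
misassignments do occur (~2% of datasets contain one) but are confined to
adjacent levels in the saturated 900–1200 region, where the relative error
of an adjacent-level slip is at most 10%; levels below 400 are always
recovered exactly. Larger tube-to-tube CVs (≥ 0.5%) start producing
900↔1000 slips (11% error), and larger rate exponents γ erase the
low-concentration kinetic contrast within a 150 s recording; both were
rejected.

### What the generator does not emulate

Real recordings contain illumination flicker and drift, shadows and
reflections on the tube, autoexposure/white-balance artifacts, ROI
misalignment, bubbles, and chemistry (substrate depletion, interferents)
that this model omits. Passing tests therefore demonstrate the *pipeline* —
preprocessing, distance, assignment, evaluation — under a plausible data
model, not field performance of the assay; the wet-lab figures of the
original study (detection limits, nanoparticle sizing, selectivity) are out
of computational reach by construction.

## Numerical choices and degenerate inputs

* Block averaging requires window and stride to be positive integer
  multiples of the sampling interval; trailing samples that do not fill a
  window are dropped by default (`partial_window_policy="keep"` emits one
  shorter-window mean).
* Relative error is undefined at a true concentration of 0; the report
  switches to absolute error for such a level (the standard grid has no 0).
* Per-level SD is the sample SD (ddof = 1), 0 for a single tube.
* CSV round trips are lossless: floats are written with shortest
  round-trip representation and parsed with `float_precision="round_trip"`.
* Frame rendering quantizes to 8 bits; ROI extraction recovers a series to
  within 1/510 per sample in the zero-noise case.
* Problem sizes: the standard evaluation (62 tubes, 30-sample, 3-channel
  series) needs 62·61/2 channel-averaged DTW alignments and runs in well
  under a second; the acceptance study repeats it on 10 independently
  seeded datasets.

## Known limitations

* Quantification is closed-world: concentrations between grid levels are
  snapped to a level, so accuracy statements are relative to the grid
  spacing.
* The DTW conventions of the original analysis (step pattern, local cost,
  normalization) are not documented anywhere; the defaults here are the
  textbook ones and are treated as configuration.
* The concentration units of the study grid are internally ambiguous in the
  source material (ppm vs ppb); the package treats levels as unit-agnostic
  numeric labels throughout.
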