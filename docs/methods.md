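# Methods

## Signal model

The package treats the nostril region of a thermal video as a periodically
forced temperature field. During exhalation warm air raises the apparent
surface temperature of the nostril interior; during inhalation cooler air
lowers it. The synthetic generator models this as a spatially uniform
interior temperature

    T(t) = baseline + amplitude · sin(2π · (rate/60) · t)

with the warm peak identified with the exhale. No specific physiological
waveform is assumed beyond periodicity; the sinusoid is chosen because it
makes every downstream expectation available in closed form (exact per-frame
mean, one strict maximum per breath, known smoothing gain). Real breathing
traces are asymmetric (sharper exhale, longer pause), which mainly shifts
peak shapes, not peak counts; rate estimation by peak timing is insensitive
to this as long as one prominent maximum per cycle survives smoothing.

## Synthetic scenes

A scene consists of one or two elliptical nostrils (default semi-axes
20×14 px, separation 90 px at the full 640×480 / 10 fps geometry) on a
uniform ambient background (default 20 °C vs 33 °C baseline). Three
confounds of field recordings are modelled explicitly because they are what
separates the aggregation statistics:

* **distance changes** — a per-frame scale factor multiplies the apparent
  radii and separation, changing ROI *area* roughly by the square of the
  factor while leaving interior temperature values untouched;
* **nostril visibility** — a per-frame count in {1, 2}; with equal
  per-nostril geometry the switch from one to two visible nostrils doubles
  the ROI pixel count;
* **sensor noise** — i.i.d. Gaussian, default sd 0.07 °C, the sensitivity
  figure of the consumer-grade thermal camera class being emulated. Noise
  is the only stochastic element; everything is reproducible bit-for-bit
  from the config seed.

A slow sinusoidal nose translation (amplitude in px, period `motion_period_s`,
default 20 s) exercises the requirement that masks be per-frame. The RGB
stream is cosmetic (flat background, darker muzzle and nostrils) because
segmentation here is oracle- or threshold-based; it can be skipped
(`render_rgb=False`) in batch experiments, in which case the scene bundle
carries no RGB stream.

What the generator does *not* model: exhaled-air plumes and turbulence,
emissivity and radiometric camera physics (emissivity is carried as
metadata only), perspective distortion, occlusion by the head, and
non-stationary breathing rates. Passing tests on these scenes therefore
demonstrate the correctness of the bookkeeping and the *relative* behaviour
of the statistics under area confounds — not detector performance or rate
accuracy on live animals.

The `render_breath_extent` variant implements breath *depth*: only a
central core holding `extent_fraction` of each nostril's area oscillates,
the rim staying at baseline. Peak temperature is then equal across extents
while the ROI mean amplitude scales with the extent. Note the rim also
clamps the ROI maximum during the cool half-cycle, so the max traces of two
scenes are identical only when both extents are strictly below 1.

## Quantization

"Optimal quantization" maps a frame's continuous temperatures onto display
intensities through a threshold that best separates object from background.
The separation criterion adopted is maximal between-class variance over an
equal-width histogram (Otsu's criterion) with `n_bins` = 256 by default;
the candidate set is the interior bin edges and ties — which arise exactly
on empty-bin plateaus between well-separated modes — break toward the lower
threshold, using a 1e-12 relative tolerance so that analytically tied
plateau values rounded differently do not flip the choice. Sub-threshold
pixels map to 0 and [threshold, max] maps linearly onto [0, 255].
Thresholding is per-frame (dynamic) by default; a per-recording pooled
threshold is available for stable scenes.

## Detection scoring

Boxes are half-open `[r0, r1) × [c0, c1)` in 0-based (row, col) pixels.
Matching is greedy in descending score order (ties by frame index, then
input order), one-to-one within each frame, and a detection is a true
positive iff IoU with an unmatched ground truth *strictly exceeds* the
threshold (at exactly 0.5 a match fails). IoU is computed on boxes by
default — mask IoU is an option — and AP uses the all-point precision
envelope. With a single object class, mAP = AP. The oracle provider
(optionally dilated/dropped ground truth) and the threshold detector
(per-frame quantization → 8-connected components filtered by area, score =
mean quantized intensity / 255) bound the two ends of detector quality that
an external instance-segmentation model would fall between; boundary-touching
components are retained.

## Trace processing

Empty-mask frames become missing values. Gaps of at most 1 s are linearly
interpolated; longer gaps (or missing edges) split the trace and the longest
contiguous segment is analysed, with its start offset reported so event
indices remain absolute. Smoothing convolves with the normalized Gaussian
window under reflected-boundary padding. Two numerical choices:

* an exactly constant segment is returned unchanged, so the unit-DC-gain
  property holds bit-exactly instead of to summation rounding;
* the peak detector's prominence floor is `min_prominence` (default 0.3)
  times the trace's 5th–95th percentile span rather than its full max−min
  range. Reflected-boundary smoothing leaves a half-window transient at
  each end of the trace whose excursion can dominate max−min when the
  breathing band is strongly attenuated (above ~50 bpm at 10 fps with the
  2 s window); the inter-percentile span equals ≈ 0.99 of the full range
  for a clean periodic signal while ignoring those transients.

Peaks must additionally be separated by `min_distance_s` (default 0.5 s,
i.e. a 120 bpm ceiling). A flag inverts polarity for conventions where the
inhale dominates. The rate rule mirrors the manual observation protocol:
with at least six peaks, the first-to-sixth-peak span covers five breaths
and `RR = 5/T₅ × 60`; with two to five peaks the fallback is
60 / (mean inter-peak interval); fewer than two peaks is an error, not a
zero.

With the default 2 s window the smoothing gain at rate f bpm and 10 fps is
approximately `exp(−½(2πσf/60·fs⁻¹)²)` with σ = 3.5 samples — about 0.55 at
30 bpm and 0.09 at 60 bpm — which is why the prominence criterion is
relative to the trace's own span rather than absolute.

## Experiments

`recovery_experiment` draws true rates uniformly from a band (default
10–60 bpm), renders one scene per recording, runs the ground-truth-mask,
mean-method pipeline, and regresses estimated on true rate by ordinary
least squares with intercept (R² = 1 − SSres/SStot, two-sided p-value for
zero slope). The default scene geometry is 160×120 at 10 fps with nostril
geometry scaled 1:4 from the full-frame defaults; the aggregation
statistics are computed on exact masks, so they are independent of the
rendering resolution, and the quarter-scale frames keep a 50-recording
batch around a minute of compute. Failed recordings are excluded from the
regression and logged.

`method_comparison` extracts all three traces from one scene and flags
artifacts. Change-points are read off the mask pixel-count series (exact in
synthetic scenes): any frame-to-frame relative jump above 20%. A level
shift is declared when the ratio of trailing to leading 5 s medians around
a change-point leaves [1/1.25, 1.25] — the operationalisation of a trace
"suddenly increasing regardless of breathing strength". Medians over 5 s
windows are robust to the breathing oscillation itself but not phase-exact,
so the measured sum ratio tracks the area ratio to within a few percent
rather than exactly. A trace whose smoothed peak-to-trough range falls
below 0.2 °C is flagged as too flat to carry a breathing signal (the max
statistic's failure mode on shallow breaths); the threshold is config-level
and applies only to the °C-valued methods in practice, since sum traces
live on a different scale.

## Defaults worth knowing

| parameter | default | unit | why |
|---|---|---|---|
| baseline_temp / amplitude | 33 / 2 | °C | nostril surface vs several-°C breath swing; amplitude is exposed, not hard-coded |
| ambient_temp | 20 | °C | indoor barn background, far from the nostril band |
| noise_sd | 0.07 | °C | stated sensitivity of the emulated camera class |
| fps, frame | 10, 640×480 | — | the emulated acquisition stream |
| smoothing window | 2 | s | shorter than the slowest breath (6 s at 10 bpm), long enough to kill pixel flicker |
| min_prominence | 0.3 | fraction | rejects noise ripple at the sensor noise level after smoothing |
| min_distance_s | 0.5 | s | 120 bpm physiological ceiling |
| IoU threshold | 0.5 | fraction | standard detection operating point; strict inequality |

## Known limitations

* The temperature validity range is fixed at the device class's −20..400 °C;
  sequences outside it are rejected rather than clipped.
* The sum statistic's units (°C·pixels) are tracked but the level-shift
  flag compares ratios only; absolute calibration is out of scope, as is
  emissivity correction.
* Rates above ~90 bpm at 10 fps approach the sampling and smoothing limits
  of the default kernel; callers should shorten the window for tachypnoea.
* The regression harness compares rates, not breath-window placement; two
  observers timing different five-breath windows of a non-stationary trace
  would disagree in ways the synthetic scenes (stationary rates) cannot
  expose.
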