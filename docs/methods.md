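# Methods

This note documents the models and numerical choices behind `nirlymph`: the
peak detector, the contractility metrics, the diameter tracker, and the
synthetic phantom that validates them. It also states what the phantom does
*not* emulate, and therefore what passing tests do and do not show about real
recordings.

## Multiscale peak detection (`nirlymph.ampd`)

Contractility traces are quasi-periodic: peak spacing drifts with
physiological state, so a fixed-window peak finder needs per-recording
tuning. The detector instead builds a local-maxima scalogram of the linearly
detrended signal `x` (length `N`): for every lag `k = 1 … L`,
`L = ⌈N/2⌉ − 1`,

```
M[k, i] = 0    if x[i] > x[i−k] and x[i] > x[i+k] (both neighbours exist)
M[k, i] = 1.5  otherwise
```

The row sums `γ_k = Σ_i M[k, i]` measure how strongly the signal expresses
lag-`k` maxima; the selected scale `λ* = argmin_k γ_k` (ties broken toward
the smallest `k`, the finest scale consistent with the minimum). Sample `i`
is a peak iff it is a strict local maximum at *every* lag `k ≤ λ*` for which
both neighbours are inside the recording; lag 1 must be testable, so the
first and last samples are never peaks. Troughs are found by running the
same detector on the negated raw signal (detrended independently), and the
merged event sequence is then forced to alternate peak/trough, keeping the
more extreme event where two of a kind are adjacent.

Numerical choices:

* **Deterministic fill.** The classical formulation fills non-maximum
  scalogram cells with `1 + r`, `r ~ U(0, 1)`. The detection criterion only
  distinguishes zero from non-zero cells, so the fill is fixed at its
  expected value 1.5; `γ`, `λ*` and the peak set become bit-reproducible
  with no change to which peaks are found.
* **Boundary lags.** Cells whose lag-`k` neighbour falls outside the
  recording keep the fill value and are excluded from the peak test (rather
  than counted as disqualifying). A peak within `λ*` of an edge is then
  judged on the lags that exist; this keeps genuine events near the
  recording boundaries detectable. Consequence: on noiseless periodic
  signals with ≥ 3 cycles, the reported peaks coincide exactly with a
  brute-force strict-local-maxima scan of the detrended signal — this
  equivalence is a standing test.
* **Detrending guard.** Least-squares line removal leaves O(1e−16) rounding
  dust on exactly linear or constant inputs, which would register as
  spurious strict extrema; residuals below `1e−12 × max(|x|, 1)` are snapped
  to zero.
* Signals shorter than 10 samples are rejected, not padded. Event indices
  refer to the original signal; downstream amplitudes use raw values.

## Contractility metrics (`nirlymph.metrics`)

* **Instantaneous mean** `m(t)`: centred moving average with an odd window of
  `round_to_odd(1.5 × median inter-peak interval)` samples — wide enough to
  average out the phasic oscillation, narrow enough to follow tonic drift.
  The residual phasic leakage of a 1.5-cycle boxcar on a pure sinusoid is
  `|sinc(1.5)| ≈ 0.21` of the oscillation amplitude; metrics are insensitive
  to this because the same `m` appears in every cycle's denominator. The
  first and last half-windows are flagged as calibration margins: cycles
  touching them are excluded from amplitude statistics. With fewer than two
  peaks the window is undefined and callers fall back to the whole-window
  mean.
* **Cycles** pair each peak with the immediately following trough;
  `%amplitude = 100·(peak − trough)/m(midpoint)` with raw (un-detrended)
  values — amplitude is a physical signal change. The per-trace % amplitude
  is the mean of the per-cycle ratios; an alternative mode
  (`amplitude_mode="window_mean"`) divides the mean raw amplitude by the
  window mean instead.
* **Frequency** counts *all* detected peaks in the window, including those
  inside the calibration margins, divided by the window length in minutes —
  counting needs no local mean, and short windows should not lose events.
* **Quiescent convention**: no peaks → frequency 0, % amplitude undefined
  (NaN), pumping score 0. A positive frequency with undefined amplitude
  leaves the score undefined rather than silently zero.
* **Pumping score** is exactly `frequency × %amplitude` (an identity checked
  by the tests, never recomputed independently downstream).
* **Treatment analysis** summarises a baseline window (default 0–2 min) and
  a post window (default 3–6 min, matching an 8-minute design with the agent
  applied at t = 2 min) and reports each metric as percent of baseline;
  tone is the ratio of the window means. Ratios over non-positive or
  undefined baselines are flagged NaN without failing the others.

All ratio metrics are invariant under positive rescaling of the trace, so
camera gain and tracer brightness drop out.

## Diameter tracking (`nirlymph.tracking`)

Geometry (supplied by the user, as ROIs are drawn on real data): a vessel
ROI of radius `r` centred on the vessel; a background ROI of radius `r/2`
centred `2r` away along the perpendicular (`normal`) direction; a
measurement line of length `3r` from the background-ROI centre through the
vessel centre to the far edge of the vessel ROI. Conventions are fixed for
bit-reproducibility: 0-based `(x, y)` pixel coordinates, a disc contains a
pixel iff its centre is within (≤) the radius, bilinear interpolation at
unit-pixel spacing along the line.

Per frame: the **moving threshold** `T = MFI_vessel / MFI_background`
adapts to tracer washout and contraction-driven brightness changes; the line
profile is normalised by the mean of its first ten samples (local
background) and samples **strictly above** `T` are counted as lumen
(`diameter = count × scale`). All supra-threshold samples count by default,
reproducing spreadsheet-style COUNTIF semantics; `mode="contiguous"`
measures the longest contiguous run instead, as a robustness option for
noisy acquisitions. Frames with non-positive background or normaliser are
marked missing; more than 10% missing aborts the run.

### Choosing the ROI radius

On an ideal tracer-filled cylinder the profile is the chord function
`c(u) = 2√((D/2)² − u²)` and the threshold equals the *mean* path over the
vessel ROI, `p̄ ≈ D²/(2r)` px for `r ≫ D/2`. Two error terms pull `r` in
opposite directions:

* **Geometric bias.** Thresholding the chord at `p̄` under-measures the
  width by `≈ p̄²/(2D) = D³/(8r²)` px — shrink it by making `r` large
  (the vessel ROI averages in background, pushing the threshold down to
  where the profile edge is steep).
* **Noise margin.** With per-pixel noise `σ = φ ×` lumen contrast
  (contrast = brightness × D), the threshold sits
  `z ≈ p̄/(φ·D) = D/(2rφ)` noise SDs above background; if `z` is small the
  unordered count picks up spurious samples along the ~`3r` background
  stretch of the line — shrink that by making `r` small.

`vessel_roi_radius(d_max_px, bias_px, noise_fraction)` returns
`r = √(D³/(8·bias))` clipped to `r ≤ D/(2.2·φ·z_margin)` with
`z_margin = 3.7` (≈10% allowance for normaliser noise), and never below
`D/2 + 1`. At `φ = 0.05` this keeps the noiseless error within 1 px and the
noisy mean absolute deviation near 1 px across D = 10–60 px for PSF σ ≤ 1 px.
The 1 px noiseless floor is the count discretisation itself (an even-width
vessel centred on a pixel row yields an odd supra-threshold count).

The ROI MFI trace (`extract_mfi_trace`, optionally background-subtracted) is
the volume-proportional modality: the chord integrates to the lumen
cross-section `π(D/2)²`, so background-subtracted MFI ∝ D².

## The phantom (`nirlymph.phantom`)

The phantom emulates a tracer-filled cylindrical vessel imaged in
fluorescence: pixel intensity is `background + brightness × path length`
(the chord), blurred by an integral-preserving Gaussian PSF (truncated at
4σ), with additive Gaussian read noise (a Poisson option exists for
shot-noise-dominated regimes). The vessel is rendered horizontal; oblique
configurations are exercised by rotating the analysis geometry, not the
image.

The diameter waveform renders contractions as smooth cosine-power dips

```
g(φ) = cos(πφ)^(2p),  φ ∈ [−½, ½) cycle phase,
```

with `p` solved so the dip's full width at half maximum equals `pulse_duty`
of the cycle (duty 0.5 recovers a raised cosine; the default 0.3 gives
`p ≈ 3`, sharper and more pulse-like). A literal pulse train with an exactly
flat inter-pulse baseline has *no* strict local maxima between contractions
and is undetectable in principle from a noiseless trace; the cosine-power
shape is equally pulsatile but has exactly one strict maximum and minimum
per cycle, which is what makes exact noiseless event recovery a meaningful
test. A pure sinusoid is retained for closed-form checks.

Normalisation: `d0` is the **time-mean** diameter and `depth` the
peak-to-trough excursion as a fraction of that mean (internally the dip
amplitude is `a_pp = depth/(1 + depth·ḡ)` with `ḡ` the cycle-average of
`g`), so the constructed per-cycle % amplitude is exactly `100·depth`.
Treatment responses are a multiplicative diameter step (`tone_step`) and a
rate factor (`freq_mult`) applied from `treatment_time` with phase kept
continuous. Ground-truth peak (half-integer phase) and trough (integer
phase) times are computed in closed form per segment. Everything is
deterministic given the seed; identical parameters give byte-identical
stacks.

Defaults mirror short in vivo acquisitions: 2.5 frames/s, 3-minute
recordings (8 minutes for treatment designs, agent at t = 2 min), 6
contractions/min, 30% depth, vessel-to-background intensity ratio well
above 6-fold.

## Validation suite (`nirlymph.benchmark`, `scripts/acceptance.py`)

Problem sizes, chosen to exercise the full acquisition conditions at desk
scale:

* **Detector vs. oracle** — 50 noiseless (quasi-)periodic traces, periods
  6–40 samples, 4–15 cycles, ±10% frequency drift, ±25% amplitude
  modulation, sinusoidal and pulsatile; exact set equality against a
  brute-force neighbour scan of the detrended signal.
* **Frequency recovery** — rates {4, 6, 6.5, 9, 12} min⁻¹ × 20 noisy
  replicates, 180 s at 2.5 samples/s; recovered peak count vs. the
  generated pulse count. Noise convention here and below:
  σ = 5% of the *oscillation amplitude* (half the peak-to-trough
  excursion, i.e. the sinusoid coefficient). Recovery trains are
  phase-centred so every ground-truth event lies at least half a period
  from the window edges — a pulse whose apex is cut by the recording
  boundary is truncated by the acquisition, not mis-detected.
* **Amplitude recovery** — the same design × depths {10, 30, 50}%; mean
  absolute error of the recovered % amplitude in percentage points. Raw
  peak-minus-trough measurement carries a small positive noise bias
  (extreme-value selection over the flat diastolic top of each cycle, of
  order the noise SD); at the 5% noise level this stays inside 2 points.
* **Diameter accuracy** — rendered static cylinders, D = 10–60 px,
  PSF σ ∈ {0.5, 1} px, geometry from `vessel_roi_radius`; noiseless
  max per-frame error, and MAD at per-pixel noise of 5% of lumen contrast.
* **Modality agreement** — one contracting rendered movie; Pearson r
  between the tracked diameter and the background-subtracted ROI MFI, and
  the difference of their frequency estimates.
* **Volume amplitude ratio** — noiseless sinusoid, depth 0.1, F ∝ D² with
  zero offset: to first order `ΔF/F ≈ 2·ΔD/D`, so the fluorescence
  % amplitude is about twice the diameter % amplitude — the volume signal
  exaggerates the one-dimensional diameter excursion, which is why MFI
  amplitudes run higher than diameter amplitudes on the same vessel.
* **Treatment workflow** — 8-minute diameter-model trace, tone step 0.66
  and frequency factor 1.6 at t = 120 s, analysed over 0–2 / 3–6 min;
  recovered tone and frequency percent-of-baseline vs. construction. The
  tone check uses the diameter modality because a diameter step `s` scales
  a volume-proportional (D²) trace by `s²`, not `s`.

`scripts/acceptance.py --seed S --out F` runs all of the above (all
randomness derived from `S`) and writes each quantity with the problem size
behind it; the whole suite takes a few seconds on one CPU.

## Limitations

The phantom is an optical idealisation: no breathing or motion artefacts, no
tissue scattering or vignetting, no valve shadows, spatially uniform tracer
concentration and contraction (no lymphangion-to-lymphangion propagation),
and a uniform background. Passing the suite demonstrates that the
algorithms recover what the model puts in — detector correctness, metric
identities, tracker geometry — not that the optical model captures any
particular microscope. On real data the dominant additional error sources
are motion of the preparation and heterogeneous perfusion; the moving
threshold absorbs slow global brightness changes but not displacement of the
vessel relative to the drawn ROIs. The tracker's output is quantised to
whole pixels, which bounds diameter accuracy at ±1 px and clips a few
percentage points off amplitudes when the contraction excursion spans only a
handful of pixels (visible in the README example: 25.3% recovered from a
30% construction at a 12 px excursion); magnification should be chosen so
the excursion spans ≳10 px, and the % fluorescence amplitude — which is not
quantised — is the more faithful amplitude read-out at low resolution.
Group-level statistics (t-tests, ANOVA, outlier rules) are deliberately out
of scope; per-vessel summaries are exported for external statistical
software.
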