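# nirlymph

Quantification of collecting lymphatic vessel (CLV) contractility from
near-infrared (NIR) fluorescence time-lapse imaging.

Collecting lymphatic vessels pump lymph by spontaneous phasic contractions of
their smooth-muscle wall. When a vessel is perfused with an NIR tracer and
imaged over time, both its inner diameter and its mean fluorescence intensity
(MFI, which scales with the lymph volume under the ROI) oscillate with every
contraction. `nirlymph` turns such recordings — multi-page grayscale TIFF
stacks, or already-extracted 1-D traces — into the standard contractility
read-outs used in lymphatic physiology and pharmacology:

* **contraction frequency** `f` (min⁻¹) — detected peaks per minute;
* **% amplitude** `A` — per contraction cycle, `100·(peak − trough)/m(t)`,
  where `m(t)` is the *instantaneous mean* of the trace (a moving average
  over ≈1.5 contraction cycles), averaged over cycles;
* **pumping score** `P = f·A` — a composite phasic-pumping efficiency index;
* **tone** — the mean trace level; post/pre-treatment tone ratios below 100%
  indicate sustained constriction.

It is written for experimentalists analysing in vivo CLV recordings (flank or
limb preparations, invasive or transcutaneous) and for methods developers who
need a fully ground-truthed synthetic test bed.

## What is inside

| module | contents |
| --- | --- |
| `nirlymph.ampd` | Automatic multiscale-based peak detection: local-maxima scalogram `M[k,i]`, scale selection `λ* = argmin_k γ_k`, all-scale peak criterion, peak/trough alternation |
| `nirlymph.tracking` | Per-frame inner-diameter tracking: vessel/background ROI means, moving threshold `T = MFI_vessel/MFI_background`, background-normalised line profile, supra-threshold pixel counting × µm/px |
| `nirlymph.metrics` | Frequency, % amplitude, pumping score, tone, Pearson r, deviation statistics, baseline-normalised treatment effects |
| `nirlymph.phantom` | Synthetic vessel movies and traces: cylinder path-length rendering (intensity ∝ lymph column), Gaussian PSF, read noise, pulsatile diameter waveforms with exact event ground truth |
| `nirlymph.io` | TIFF stacks in; trace/cycle/summary/treatment CSVs and JSON run manifests out |
| `nirlymph.cli` | `nirlymph simulate / track / quantify / compare` |
| `nirlymph.benchmark` | The phantom-based validation suite used by the tests and `scripts/acceptance.py` |

## Worked example

Simulate a 3-minute recording (2.5 frames/s) of an 80 µm vessel contracting
6 times per minute with 30% amplitude, track it, and quantify:

```sh
nirlymph simulate --out vessel.tif --d0 80 --scale 2 --duration 180 \
    --fps 2.5 --freq 6 --depth 0.3 --noise 5 --seed 1
# -> stack=vessel.tif truth=vessel.truth.csv params=vessel.params.json

nirlymph track --stack vessel.tif --fps 2.5 --scale 2.0 \
    --center-x 166 --center-y 409 --normal-angle -90 --radius 162 \
    --out-dir tracked
nirlymph quantify --trace tracked/diameter_trace.csv --out-dir results
cat results/summary.csv
```

```
trace,window_start_s,window_end_s,frequency_per_min,pct_amplitude,pumping_score,mean_level,n_cycles,amplitude_undefined
diameter_trace,0.0,180.0...,5.999999999999968,25.250067472389574,151.50040483433665,79.64,16,0
```

The frequency is recovered exactly (6.0 min⁻¹ from 18 detected peaks in
3 min); the mean tracked diameter is 79.64 µm (true mean 80 µm); the
% amplitude reads 25.3% against the constructed 30% because the pixel count
quantises the 12 px contraction excursion (see `docs/methods.md`). Comparing
the tracked trace with the generator's ground truth:

```sh
nirlymph compare --trace-a tracked/diameter_trace.csv --trace-b truth_trace.csv
```

```
metric,value
pearson_r,0.9933081288628528
mad,1.180204092471532
rmsd,1.2968607473161946
```

i.e. the tracker follows the true diameter with a mean absolute error of
1.2 µm (0.6 px) on this noisy phantom. The geometry numbers above come from
`vessel.params.json`, which `simulate` writes alongside the stack; for real
recordings you supply the ROI centre, the direction perpendicular to the
vessel axis, the ROI radius and the µm/px scale yourself (the helper
`nirlymph.tracking.vessel_roi_radius` suggests a radius, and
`suggest_normal` a perpendicular direction).

For treatment experiments (8-minute recordings with an agent applied at
t = 2 min), `nirlymph quantify --treatment` compares the 0–2 min baseline
window with the 3–6 min post window and reports each metric as a percent of
baseline; windows are configurable with `--baseline` / `--post`.

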