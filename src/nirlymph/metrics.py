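"""Contractility outcome measures.

From a contractility trace (vessel inner diameter or ROI mean fluorescence
intensity over time) with detected peaks and troughs, this module computes
the standard phasic and tonic read-outs:

* **frequency** — peaks per minute inside the analysis window;
* **% amplitude** — per contraction cycle, 100 * (peak - trough) divided by
  the *instantaneous mean* (a slowly varying local mean of the trace), then
  averaged over cycles.  Expressing amplitude relative to the local mean
  makes the measure independent of brightness and of vessel size;
* **pumping score** — frequency x % amplitude, a composite efficiency index;
* **tone** — the mean trace level; a post/pre-treatment ratio below 100%
  indicates sustained constriction (reduced lumen volume).

Treatment responses are expressed as percent of a baseline window
(conventionally 0-2 min pre-treatment vs. 3-6 min post-treatment of an
8-minute recording with the agent applied at t = 2 min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import pearsonr

from .ampd import PeakTroughSet, detect_peaks_and_troughs
from .errors import InvalidInputError, UndefinedMeanError
from .trace import Trace

#: Moving-average span for the instantaneous mean, in units of the median
#: inter-peak interval.  1.5 cycles averages out the phasic oscillation while
#: still following tonic drift.
MEAN_WINDOW_CYCLES = 1.5


def round_to_odd(v: float) -> int:
    """Nearest odd integer to v (>= 1); used for centred moving averages."""
    return max(1, 2 * int(round((v - 1) / 2)) + 1)


@dataclass(frozen=True)
class InstantaneousMean:
    """Centred moving average of a trace plus its edge exclusion width.

    The first and last ``half_window`` samples are edge regions where the
    centred window is incomplete; cycles touching them are excluded from
    amplitude statistics (the shaded calibration margins on diagnostic
    plots).
    """

    values: np.ndarray
    half_window: int

    def excluded(self, index: int) -> bool:
        n = self.values.size
        return index < self.half_window or index > n - 1 - self.half_window


@dataclass(frozen=True)
class CycleMeasurement:
    """One contraction cycle: a peak paired with the following trough."""

    peak_index: int
    trough_index: int
    peak_value: float
    trough_value: float
    local_mean: float
    pct_amplitude: float


@dataclass(frozen=True)
class ContractilitySummary:
    """Contractility metrics for one trace over one analysis window.

    ``pct_amplitude`` (and hence ``pumping_score`` when frequency > 0) is NaN
    when no complete interior cycle exists; a quiescent trace (no peaks)
    yields frequency 0 and pumping score 0.
    """

    frequency: float  # contractions / min
    pct_amplitude: float  # percent of instantaneous mean (NaN if undefined)
    pumping_score: float  # frequency x pct_amplitude
    mean_level: float  # mean trace value over the window (tone basis)
    n_cycles: int
    window: tuple[float, float]  # [t_start, t_end] seconds


@dataclass(frozen=True)
class TreatmentEffect:
    """Post-treatment metrics expressed as percent of baseline (100% = no change)."""

    baseline: ContractilitySummary
    post: ContractilitySummary
    frequency_pct: float
    amplitude_pct: float
    pumping_pct: float
    tone_pct: float


def instantaneous_mean(x: Trace | np.ndarray, events: PeakTroughSet) -> InstantaneousMean:
    """Centred moving average with a window of 1.5 median inter-peak intervals.

    Needs at least 2 peaks to estimate a period; otherwise raises
    :class:`UndefinedMeanError` and the caller falls back to the whole-window
    mean.
    """
    v = x.values if isinstance(x, Trace) else np.asarray(x, dtype=float)
    peaks = events.peak_indices
    if peaks.size < 2:
        raise UndefinedMeanError("at least 2 peaks needed for an inter-peak interval")
    med = float(np.median(np.diff(np.sort(peaks))))
    w = round_to_odd(MEAN_WINDOW_CYCLES * med)
    w = min(w, round_to_odd(float(v.size)))  # never wider than the trace
    smoothed = uniform_filter1d(v, size=w, mode="nearest")
    return InstantaneousMean(values=smoothed, half_window=w // 2)


def measure_cycles(
    x: Trace | np.ndarray,
    events: PeakTroughSet,
    inst_mean: InstantaneousMean,
) -> list[CycleMeasurement]:
    """Pair each peak with the immediately following trough and measure it.

    Cycles whose peak or trough falls in an edge exclusion region are
    dropped, as are (degenerate) cycles with non-positive local mean.
    Amplitudes use raw trace values; the local mean is evaluated at the
    midpoint sample between peak and trough.
    """
    v = x.values if isinstance(x, Trace) else np.asarray(x, dtype=float)
    seq = events.events()
    cycles: list[CycleMeasurement] = []
    for (i, kind), (j, kind2) in zip(seq, seq[1:]):
        if kind != "peak" or kind2 != "trough":
            continue
        if inst_mean.excluded(i) or inst_mean.excluded(j):
            continue
        mid = (i + j) // 2
        lm = float(inst_mean.values[mid])
        if lm <= 0:
            continue
        pv, tv = float(v[i]), float(v[j])
        cycles.append(
            CycleMeasurement(
                peak_index=i,
                trough_index=j,
                peak_value=pv,
                trough_value=tv,
                local_mean=lm,
                pct_amplitude=100.0 * (pv - tv) / lm,
            )
        )
    return cycles


def contraction_frequency(events: PeakTroughSet | np.ndarray, duration_s: float) -> float:
    """Peaks per minute: (number of peaks) / (window duration in minutes).

    All peaks count, including those in edge exclusion regions — counting
    needs no local mean, and short windows would otherwise lose events.
    """
    if not (np.isfinite(duration_s) and duration_s > 0):
        raise InvalidInputError("window duration must be positive")
    peaks = events.peak_indices if isinstance(events, PeakTroughSet) else np.asarray(events)
    return float(peaks.size) / (duration_s / 60.0)


def percent_amplitude(cycles: list[CycleMeasurement]) -> float:
    """Mean per-cycle % amplitude; NaN (undefined) for an empty cycle list."""
    if not cycles:
        return math.nan
    return float(np.mean([c.pct_amplitude for c in cycles]))


def pumping_score(frequency: float, pct_amplitude: float) -> float:
    """frequency x % amplitude.

    Quiescent convention: zero frequency with undefined amplitude scores 0
    (no pumping); a positive frequency with undefined amplitude stays
    undefined (NaN).
    """
    if math.isnan(pct_amplitude):
        return 0.0 if frequency == 0 else math.nan
    return frequency * pct_amplitude


def tone_change(pre: Trace | np.ndarray, post: Trace | np.ndarray) -> float:
    """100 x mean(post) / mean(pre); < 100% indicates constriction."""
    pre_v = pre.values if isinstance(pre, Trace) else np.asarray(pre, dtype=float)
    post_v = post.values if isinstance(post, Trace) else np.asarray(post, dtype=float)
    if pre_v.size == 0 or post_v.size == 0:
        raise InvalidInputError("tone change needs non-empty traces")
    m = float(np.mean(pre_v))
    if m <= 0:
        raise InvalidInputError("pre-treatment mean must be positive")
    return 100.0 * float(np.mean(post_v)) / m


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("inputs must be equal-length 1-D vectors")
    if a.size < 3:
        raise InvalidInputError("correlation needs at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvalidInputError("correlation undefined for zero-variance input")
    return float(pearsonr(a, b).statistic)


def deviation_stats(auto: np.ndarray, manual: np.ndarray) -> tuple[float, float]:
    """Mean absolute deviation and root-mean-square deviation of paired values."""
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1 or auto.size == 0:
        raise InvalidInputError("inputs must be equal-length non-empty vectors")
    diff = auto - manual
    mad = float(np.mean(np.abs(diff)))
    rmsd = float(np.sqrt(np.mean(diff**2)))
    return mad, rmsd


def summarize_trace(
    trace: Trace,
    window: tuple[float, float] | None = None,
    amplitude_mode: str = "per_cycle",
) -> ContractilitySummary:
    """Full analysis of one trace over one window.

    Runs detection -> alternation -> instantaneous mean -> cycle
    measurement -> frequency / % amplitude / pumping score / mean level.

    ``amplitude_mode``: ``"per_cycle"`` (default) averages the per-cycle
    amplitude ratios; ``"window_mean"`` instead divides the mean raw
    peak-trough amplitude by the window mean.
    """
    if amplitude_mode not in ("per_cycle", "window_mean"):
        raise InvalidInputError(f"unknown amplitude_mode {amplitude_mode!r}")
    sub = trace.window(*window) if window is not None else trace
    events = detect_peaks_and_troughs(sub)
    freq = contraction_frequency(events, sub.duration)
    mean_level = float(np.mean(sub.values))
    try:
        inst = instantaneous_mean(sub, events)
        cycles = measure_cycles(sub, events, inst)
    except UndefinedMeanError:
        cycles = []
    if amplitude_mode == "per_cycle" or not cycles:
        amp = percent_amplitude(cycles)
    else:
        raw = np.mean([c.peak_value - c.trough_value for c in cycles])
        amp = 100.0 * float(raw) / mean_level if mean_level > 0 else math.nan
    score = pumping_score(freq, amp)
    t_start = sub.t0
    t_end = sub.t0 + sub.duration
    return ContractilitySummary(
        frequency=freq,
        pct_amplitude=amp,
        pumping_score=score,
        mean_level=mean_level,
        n_cycles=len(cycles),
        window=(t_start, t_end),
    )


def _ratio_pct(post: float, base: float) -> float:
    if not np.isfinite(base) or base <= 0 or not np.isfinite(post):
        return math.nan
    return 100.0 * post / base


def normalize_to_baseline(
    baseline: ContractilitySummary, post: ContractilitySummary
) -> TreatmentEffect:
    """Express post-treatment metrics as percent of baseline (baseline = 100%).

    Any ratio with a non-positive or undefined baseline metric is NaN; the
    remaining ratios are still computed.
    """
    return TreatmentEffect(
        baseline=baseline,
        post=post,
        frequency_pct=_ratio_pct(post.frequency, baseline.frequency),
        amplitude_pct=_ratio_pct(post.pct_amplitude, baseline.pct_amplitude),
        pumping_pct=_ratio_pct(post.pumping_score, baseline.pumping_score),
        tone_pct=_ratio_pct(post.mean_level, baseline.mean_level),
    )


def analyze_treatment(
    trace: Trace,
    baseline_window: tuple[float, float] = (0.0, 120.0),
    post_window: tuple[float, float] = (180.0, 360.0),
    amplitude_mode: str = "per_cycle",
) -> TreatmentEffect:
    """Baseline-vs-post analysis of a treatment recording.

    Default windows follow the 8-minute design with treatment at t = 2 min:
    baseline 0-2 min, post 3-6 min (1-4 min after application).
    """
    base = summarize_trace(trace, baseline_window, amplitude_mode)
    post = summarize_trace(trace, post_window, amplitude_mode)
    return normalize_to_baseline(base, post)
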