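"""Synthetic vessel phantoms with known ground truth.

The generator emulates a tracer-filled cylindrical lymphatic vessel imaged
in fluorescence: the vessel is rendered horizontally as its projected path
length (the chord function, so pixel intensity is proportional to the lymph
column under each pixel and ROI fluorescence is proportional to lumen
volume), blurred by a Gaussian point-spread function, placed on a uniform
autofluorescent background and corrupted by additive Gaussian read noise.

The diameter waveform is pulsatile: contractions are rendered as smooth
cosine-power dips

    g(phi) = cos(pi * phi) ** (2 p),   phi in [-1/2, 1/2) cycle phase,

whose full width at half maximum is ``pulse_duty`` of the cycle (p is solved
from the duty).  Unlike a literal pulse train with a flat inter-pulse
baseline, this shape has exactly one strict local maximum and minimum per
cycle, so noiseless traces remain analysable by a peak detector.  A pure
sinusoid (``waveform="sinusoid"``) is kept for closed-form checks.

Normalisation: ``d0`` is the *time-mean* inner diameter and ``depth`` is the
peak-to-trough excursion as a fraction of that mean, i.e. the true per-cycle
% amplitude of the diameter trace is exactly ``100 * depth``.  A tonic
treatment response is modelled as a multiplicative step ``tone_step`` on the
diameter and a factor ``freq_mult`` on the contraction rate at
``treatment_time`` (phase is kept continuous across the step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import gammaln

from .errors import InvalidInputError
from .trace import Trace
from .tracking import VesselGeometry, vessel_roi_radius


@dataclass(frozen=True)
class ContractionWaveformParams:
    """Ground-truth diameter waveform parameters.

    ``d0`` time-mean inner diameter (um); ``depth`` peak-to-trough fraction
    of the mean (0 <= depth < 1); ``frequency_per_min`` contraction rate;
    ``pulse_duty`` dip FWHM as a fraction of the cycle; ``phase`` initial
    cycle phase (dips centred at integer phase, diastolic peaks at
    half-integer phase); ``tone_step``/``freq_mult`` applied from
    ``treatment_time`` onward; no contractions before ``quiescent_until``.
    """

    d0: float = 100.0
    depth: float = 0.3
    frequency_per_min: float = 6.0
    waveform: str = "pulse"  # "pulse" | "sinusoid"
    pulse_duty: float = 0.3
    phase: float = 0.15
    tone_step: float = 1.0
    freq_mult: float = 1.0
    treatment_time: float | None = None
    quiescent_until: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and np.isfinite(self.d0)):
            raise InvalidInputError("d0 must be positive")
        if not (0 <= self.depth < 1):
            raise InvalidInputError("depth must be in [0, 1)")
        if self.frequency_per_min < 0:
            raise InvalidInputError("frequency must be >= 0")
        if self.waveform not in ("pulse", "sinusoid"):
            raise InvalidInputError(f"unknown waveform {self.waveform!r}")
        if not (0 < self.pulse_duty <= 0.9):
            raise InvalidInputError("pulse_duty must be in (0, 0.9]")
        if self.tone_step <= 0 or self.freq_mult <= 0:
            raise InvalidInputError("tone_step and freq_mult must be positive")
        if self.quiescent_until < 0:
            raise InvalidInputError("quiescent_until must be >= 0")

    @property
    def pulse_exponent(self) -> float:
        """Cosine power p such that the dip FWHM equals pulse_duty cycles."""
        return -1.0 / (2.0 * math.log2(math.cos(math.pi * self.pulse_duty / 2)))

    @property
    def dip_mean(self) -> float:
        """Cycle-average of the dip shape g (gbar)."""
        if self.waveform == "sinusoid":
            return 0.5
        p = self.pulse_exponent
        return float(np.exp(gammaln(p + 0.5) - gammaln(p + 1.0)) / math.sqrt(math.pi))

    @property
    def dip_amplitude(self) -> float:
        """Dip depth a_pp relative to the diastolic peak, solved so the
        peak-to-trough excursion is ``depth`` of the time-mean diameter."""
        return self.depth / (1.0 + self.depth * self.dip_mean)


@dataclass(frozen=True)
class WaveformTruth:
    """Sampled ground-truth diameters plus exact event times."""

    times: np.ndarray
    diameters_um: np.ndarray
    peak_times: np.ndarray
    trough_times: np.ndarray
    params: ContractionWaveformParams

    @property
    def n_pulses(self) -> int:
        return int(self.peak_times.size)

    def to_trace(self, frame_rate: float) -> Trace:
        return Trace(self.diameters_um, frame_rate, units="um")


def _dip_shape(params: ContractionWaveformParams, phi: np.ndarray) -> np.ndarray:
    """Dip shape g in [0, 1]; g = 1 at integer phase (full contraction)."""
    frac = phi - np.round(phi)  # wrapped to [-0.5, 0.5)
    if params.waveform == "sinusoid":
        return 0.5 * (1.0 + np.cos(2 * math.pi * frac))
    return np.cos(math.pi * frac) ** (2.0 * params.pulse_exponent)


def _phase(params: ContractionWaveformParams, t: np.ndarray) -> np.ndarray:
    """Cycle phase, continuous across the treatment frequency step."""
    f1 = params.frequency_per_min / 60.0
    q = params.quiescent_until
    tt = params.treatment_time
    active = np.maximum(np.asarray(t, dtype=float) - q, 0.0)
    if tt is None or params.freq_mult == 1.0:
        return params.phase + f1 * active
    t1 = max(tt - q, 0.0)  # active time spent at the baseline rate
    pre = np.minimum(active, t1)
    post = np.maximum(active - t1, 0.0)
    return params.phase + f1 * pre + f1 * params.freq_mult * post


def _event_times(
    params: ContractionWaveformParams, duration: float, offset: float
) -> np.ndarray:
    """Exact times in (0, duration) where the phase equals offset (mod 1)."""
    f1 = params.frequency_per_min / 60.0
    if f1 == 0 or params.depth == 0:
        return np.array([])
    q = params.quiescent_until
    tt = params.treatment_time
    f2 = f1 * params.freq_mult
    # segment boundaries in (time, phase-at-start, rate)
    segs: list[tuple[float, float, float, float]] = []  # (t_start, t_end, phi_start, rate)
    if tt is not None and q < tt < duration:
        segs.append((q, tt, params.phase, f1))
        segs.append((tt, duration, params.phase + f1 * (tt - q), f2))
    else:
        segs.append((q, duration, params.phase, f1))
    times: list[float] = []
    for t_start, t_end, phi0, rate in segs:
        if t_end <= t_start or rate <= 0:
            continue
        m_lo = math.ceil(phi0 - offset - 1e-12)
        m_hi = math.floor(phi0 + rate * (t_end - t_start) - offset + 1e-12)
        for m in range(m_lo, m_hi + 1):
            t = t_start + (m + offset - phi0) / rate
            if t_start <= t < t_end and 0.0 < t < duration:
                times.append(t)
    return np.array(sorted(set(np.round(times, 12))))


def _tone(params: ContractionWaveformParams, t: np.ndarray) -> np.ndarray:
    tone = np.ones_like(np.asarray(t, dtype=float))
    if params.treatment_time is not None:
        tone[np.asarray(t) >= params.treatment_time] = params.tone_step
    return tone


def contraction_waveform(
    params: ContractionWaveformParams, frame_rate: float, duration: float
) -> WaveformTruth:
    """Sample the ground-truth diameter waveform.

    Returns per-frame true diameters at ``round(duration * frame_rate)``
    frames plus the exact (continuous-time) peak and trough times.
    Diastolic peaks sit at half-integer phase, contraction troughs at
    integer phase.  Raises for parameters that would drive D(t) <= 0.
    """
    if not (frame_rate > 0 and duration > 0):
        raise InvalidInputError("frame rate and duration must be positive")
    n = int(round(duration * frame_rate))
    if n < 2:
        raise InvalidInputError("duration too short for the frame rate")
    t = np.arange(n) / frame_rate
    a = params.dip_amplitude
    gbar = params.dip_mean
    denom = 1.0 - a * gbar
    g = _dip_shape(params, _phase(params, t))
    g[t < params.quiescent_until] = gbar  # quiescent: hold the mean level
    if params.frequency_per_min == 0 or params.depth == 0:
        g = np.full_like(t, gbar)
    d = params.d0 * _tone(params, t) * (1.0 - a * g) / denom
    if np.any(d <= 0):
        raise InvalidInputError("waveform parameters drive the diameter to <= 0")
    peaks = _event_times(params, duration, offset=0.5)
    troughs = _event_times(params, duration, offset=0.0)
    return WaveformTruth(
        times=t, diameters_um=d, peak_times=peaks, trough_times=troughs, params=params
    )


@dataclass(frozen=True)
class VesselPhantomParams:
    """Optics and acquisition parameters of the rendered movie.

    ``brightness`` is intensity per micrometre of tracer path length;
    ``background`` the uniform autofluorescence level; ``noise_sigma`` the
    additive Gaussian read-noise standard deviation (camera units).
    Defaults mirror short contractility acquisitions (2.5 frames/s, 3 min).
    """

    width: int = 320
    height: int = 528
    axis_row: float = 376.0
    scale: float = 2.0
    brightness: float = 8.0
    background: float = 200.0
    psf_sigma: float = 1.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    frame_rate: float = 2.5
    duration: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise InvalidInputError("image must be at least 8 x 8")
        if not (0 <= self.axis_row <= self.height - 1):
            raise InvalidInputError("axis_row outside the image")
        if self.scale <= 0 or self.brightness < 0 or self.background < 0:
            raise InvalidInputError("scale must be > 0; brightness/background >= 0")
        if self.psf_sigma < 0 or self.noise_sigma < 0:
            raise InvalidInputError("psf_sigma and noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise InvalidInputError(f"unknown noise model {self.noise_model!r}")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise InvalidInputError("frame rate and duration must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class PhantomMovie:
    """Rendered stack plus the ground truth that produced it."""

    stack: np.ndarray  # uint16, (frames, height, width)
    truth: WaveformTruth
    optics: VesselPhantomParams

    def metadata(self) -> dict:
        meta = {"optics": asdict(self.optics), "waveform": asdict(self.truth.params)}
        meta["n_frames"] = int(self.stack.shape[0])
        return meta


def _column_profile(d_um: float, optics: VesselPhantomParams) -> np.ndarray:
    """Noiseless blurred intensity of one image column (vessel horizontal)."""
    radius_um = d_um / 2.0
    rows = np.arange(optics.height, dtype=float)
    u = (rows - optics.axis_row) * optics.scale  # um from the vessel axis
    inside = np.abs(u) < radius_um
    path = np.zeros(optics.height)
    path[inside] = 2.0 * np.sqrt(radius_um**2 - u[inside] ** 2)
    col = optics.background + optics.brightness * path
    if optics.psf_sigma > 0:
        col = gaussian_filter1d(col, optics.psf_sigma / 1.0, mode="nearest", truncate=4.0)
    return col


def render_frame(
    d_um: float, optics: VesselPhantomParams, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one frame (float64): chord path length x brightness on a
    uniform background, Gaussian-blurred, plus optional noise.

    The lumen cross-section is a circle of diameter ``d_um`` centred on
    ``axis_row``; pixel intensity before blur is
    ``background + brightness * 2 sqrt((D/2)^2 - y^2)``.
    """
    if not (d_um > 0 and np.isfinite(d_um)):
        raise InvalidInputError("diameter must be positive")
    half_px = d_um / (2.0 * optics.scale)
    if optics.axis_row - half_px < 0 or optics.axis_row + half_px > optics.height - 1:
        raise InvalidInputError("vessel wider than the image")
    frame = np.tile(_column_profile(d_um, optics)[:, None], (1, optics.width))
    if rng is not None:
        if optics.noise_model == "poisson" and optics.noise_sigma > 0:
            # shot noise with variance ~ signal, scaled to noise_sigma at the
            # background level
            gain = optics.noise_sigma**2 / max(optics.background, 1e-9)
            frame = rng.poisson(frame / gain) * gain
        elif optics.noise_sigma > 0:
            frame = frame + rng.normal(0.0, optics.noise_sigma, size=frame.shape)
    return frame


def generate_movie(
    wave: ContractionWaveformParams, optics: VesselPhantomParams
) -> PhantomMovie:
    """Render a full ground-truthed movie (uint16 stack).

    Byte-identical for identical parameters and seed; frames are quantised
    by rounding and clipping to the 16-bit range.
    """
    truth = contraction_waveform(wave, optics.frame_rate, optics.duration)
    rng = np.random.default_rng(optics.seed)
    n = truth.diameters_um.size
    stack = np.empty((n, optics.height, optics.width), dtype=np.uint16)
    for i, d in enumerate(truth.diameters_um):
        frame = render_frame(float(d), optics, rng=rng)
        stack[i] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)
    return PhantomMovie(stack=stack, truth=truth, optics=optics)


def default_geometry(
    wave: ContractionWaveformParams,
    optics: VesselPhantomParams,
    bias_px: float = 0.4,
    noise_fraction: float = 0.0,
) -> VesselGeometry:
    """Vessel ROI geometry matched to a rendered phantom.

    The ROI radius comes from :func:`nirlymph.tracking.vessel_roi_radius`
    applied to the maximum (diastolic) diameter (pass the acquisition's
    ``noise_fraction`` to trade bias for threshold margin under noise); the
    normal points up (toward low row numbers), where :func:`plan_optics`
    leaves room for the background ROI.
    """
    d_max_px = wave.d0 * (1.0 + wave.depth * wave.dip_mean) / optics.scale
    r = vessel_roi_radius(d_max_px, bias_px, noise_fraction)
    return VesselGeometry(
        center=(optics.width / 2.0, optics.axis_row),
        normal=(0.0, -1.0),
        r=float(r),
        scale=optics.scale,
    )


def plan_optics(
    wave: ContractionWaveformParams,
    scale: float = 2.0,
    bias_px: float = 0.4,
    noise_fraction: float = 0.0,
    margin: int = 4,
    **overrides,
) -> VesselPhantomParams:
    """Size the phantom image so the matched ROI geometry fits.

    The background ROI centre sits 2r above the vessel axis (disc top at
    2.5r) and the measurement line ends r below it, so the image height is
    about 3.5r plus margins.  ``bias_px`` / ``noise_fraction`` must match
    the values later given to :func:`default_geometry`.  Extra keyword
    arguments override any :class:`VesselPhantomParams` field except the
    geometry-derived ones.
    """
    d_max_px = wave.d0 * (1.0 + wave.depth * wave.dip_mean) / scale
    r = vessel_roi_radius(d_max_px, bias_px, noise_fraction)
    axis_row = math.ceil(2.5 * r) + margin
    height = axis_row + r + 1 + margin
    width = 2 * r + 2 * margin
    fields = dict(
        width=int(width),
        height=int(height),
        axis_row=float(axis_row),
        scale=scale,
    )
    fields.update(overrides)
    return VesselPhantomParams(**fields)


def generate_traces(
    wave: ContractionWaveformParams,
    model: str = "diameter",
    noise_sigma: float = 0.0,
    frame_rate: float = 2.5,
    duration: float = 180.0,
    seed: int | None = None,
    fluor_coeff: float = 0.01,
    fluor_offset: float = 0.0,
) -> tuple[Trace, WaveformTruth]:
    """1-D shortcut: sample the waveform directly as a trace.

    ``model="diameter"`` returns D(t) in um; ``model="fluorescence"``
    returns ``offset + coeff * D(t)^2``, emulating a background-subtracted
    ROI mean fluorescence proportional to lumen volume.  ``noise_sigma`` is
    additive Gaussian, in trace units.
    """
    if model not in ("diameter", "fluorescence"):
        raise InvalidInputError(f"unknown trace model {model!r}")
    truth = contraction_waveform(wave, frame_rate, duration)
    if model == "diameter":
        values = truth.diameters_um.copy()
        units = "um"
    else:
        values = fluor_offset + fluor_coeff * truth.diameters_um**2
        units = "a.u."
    if noise_sigma > 0:
        rng = np.random.default_rng(wave.seed if seed is None else seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.size)
    return Trace(values, frame_rate, units=units), truth
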