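"""Automatic multiscale-based peak detection (AMPD) for quasi-periodic traces.

Phasic lymphatic contractions produce quasi-periodic diameter and MFI traces
whose peak-to-peak spacing drifts, so a fixed-window peak finder needs manual
tuning per recording.  AMPD instead builds a local-maxima scalogram: for every
lag k it marks the samples that exceed both neighbours at distance k, picks
the lag lambda* at which the signal is "most periodic" (the row with the most
marks), and reports the samples that are local maxima at *every* lag up to
lambda*.  The only free parameter, the scale, is thus selected from the data.

Determinism: the classical formulation fills non-maximum scalogram cells with
1 + r, r uniform on [0, 1].  Because the detection criterion only ever
distinguishes zero from non-zero cells, the random fill is replaced here by
its expected value 1.5, which makes the row sums (gamma) and the selected
scale reproducible bit-for-bit without changing which peaks are found.

Boundary handling: cells whose lag-k neighbour falls outside the recording
keep the fill value, and the peak criterion only tests lags for which both
neighbours exist.  A peak therefore needs at least its two immediate
neighbours; peaks closer than lambda* to an edge are tested against the
one-sided lags that do exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import InvalidInputError
from .trace import Trace

#: Deterministic fill for non-maximum scalogram cells (expected value of the
#: classical 1 + uniform(0, 1) fill).
FILL_VALUE = 1.5

#: Minimum trace length the detector accepts.
MIN_SAMPLES = 10

ArrayLike = Union[np.ndarray, "Trace", list, tuple]


def _values(x: ArrayLike) -> np.ndarray:
    if isinstance(x, Trace):
        v = x.values
    else:
        v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise InvalidInputError("signal must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("signal values must all be finite")
    return v.astype(float, copy=False)


@dataclass(frozen=True)
class ScaleSelection:
    """Diagnostics of the multiscale scale choice.

    Attributes
    ----------
    gamma : np.ndarray
        Row sums of the scalogram, indexed by scale k = 1..max_scale
        (``gamma[k-1]`` is the sum for lag k).  Small gamma means many
        lag-k maxima.
    lambda_star : int
        Selected scale: the smallest k attaining the minimum of gamma.
    max_scale : int
        Largest lag considered, ceil(N/2) - 1.
    """

    gamma: np.ndarray
    lambda_star: int
    max_scale: int

    def __post_init__(self) -> None:
        if not (1 <= self.lambda_star <= self.max_scale):
            raise InvalidInputError("lambda_star outside [1, max_scale]")


@dataclass(frozen=True)
class PeakTroughSet:
    """Detected contraction events on one trace.

    ``peak_indices`` / ``trough_indices`` refer to sample positions of the
    original (un-detrended) trace and, after alternation enforcement,
    strictly interleave.
    """

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    scale_peaks: ScaleSelection | None = None
    scale_troughs: ScaleSelection | None = None

    @property
    def n_peaks(self) -> int:
        return int(self.peak_indices.size)

    def events(self) -> list[tuple[int, str]]:
        """Merged (index, kind) sequence sorted by sample index."""
        ev = [(int(i), "peak") for i in self.peak_indices]
        ev += [(int(i), "trough") for i in self.trough_indices]
        ev.sort(key=lambda e: (e[0], e[1]))
        return ev


def detrend_linear(x: ArrayLike) -> np.ndarray:
    """Remove the least-squares straight line from a signal.

    Returns ``x`` minus its first-order polynomial fit; the output has
    (numerically) zero mean.  Requires at least 2 samples.

    Residuals below the floating-point noise floor of the input are snapped
    to exactly zero, so that perfectly linear or constant signals come out
    exactly flat instead of carrying rounding dust that would register as
    spurious strict local extrema.
    """
    v = _values(x)
    if v.size < 2:
        raise InvalidInputError("detrending needs at least 2 samples")
    t = np.arange(v.size, dtype=float)
    coeffs = np.polyfit(t, v, 1)
    resid = v - np.polyval(coeffs, t)
    tol = 1e-12 * max(float(np.abs(v).max()), 1.0)
    resid[np.abs(resid) < tol] = 0.0
    return resid


def max_scale(n: int) -> int:
    """Largest lag of the scalogram for a length-n signal: ceil(n/2) - 1."""
    return int(np.ceil(n / 2)) - 1


def local_maxima_scalogram(x: ArrayLike) -> np.ndarray:
    """Build the L x N local-maxima scalogram of a (detrended) signal.

    ``M[k-1, i] == 0`` iff both neighbours at lag k exist and
    ``x[i] > x[i-k]`` and ``x[i] > x[i+k]`` (strict); every other cell holds
    :data:`FILL_VALUE`.  L = ceil(N/2) - 1.
    """
    v = _values(x)
    n = v.size
    if n < MIN_SAMPLES:
        raise InvalidInputError(f"scalogram needs at least {MIN_SAMPLES} samples")
    L = max_scale(n)
    M = np.full((L, n), FILL_VALUE)
    for k in range(1, L + 1):
        centre = v[k : n - k]
        is_max = (centre > v[: n - 2 * k]) & (centre > v[2 * k :])
        row = M[k - 1, k : n - k]
        row[is_max] = 0.0
    return M


def select_scale(M: np.ndarray) -> ScaleSelection:
    """Pick the dominant scale: the row of M with the smallest sum.

    Ties are broken toward the smallest k (the finest scale consistent with
    the minimum).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise InvalidInputError("scalogram must be a non-empty 2-D matrix")
    gamma = M.sum(axis=1)
    lam = int(np.argmin(gamma)) + 1  # np.argmin returns the first minimum
    return ScaleSelection(gamma=gamma, lambda_star=lam, max_scale=M.shape[0])


def find_peaks_ampd(x: ArrayLike) -> tuple[np.ndarray, ScaleSelection]:
    """Detect peaks of a quasi-periodic signal.

    The signal is linearly detrended, the scalogram built, the scale
    lambda* selected, and sample i is reported as a peak iff it is a strict
    local maximum at every lag k = 1..lambda* for which both neighbours
    i-k and i+k are inside the recording (lag 1 must be testable, so the
    first and last samples are never peaks).

    Returns the sorted peak indices (positions on the original signal) and
    the :class:`ScaleSelection` diagnostics.  A flat signal yields an empty
    index set, not an error.
    """
    v = _values(x)
    n = v.size
    if n < MIN_SAMPLES:
        raise InvalidInputError(f"peak detection needs at least {MIN_SAMPLES} samples")
    d = detrend_linear(v)
    M = local_maxima_scalogram(d)
    sel = select_scale(M)
    lam = sel.lambda_star
    zeros = M[:lam] == 0.0
    idx = np.arange(n)
    # number of testable lags per column: both neighbours must exist
    kmax = np.minimum(lam, np.minimum(idx, n - 1 - idx))
    n_zero = np.cumsum(zeros, axis=0)
    ok = kmax >= 1
    cols = np.flatnonzero(ok)
    all_zero = n_zero[kmax[cols] - 1, cols] == kmax[cols]
    peaks = cols[all_zero]
    return peaks.astype(int), sel


def enforce_alternation(
    peaks: np.ndarray, troughs: np.ndarray, x: ArrayLike
) -> tuple[np.ndarray, np.ndarray]:
    """Make the merged peak/trough sequence strictly alternate.

    Where two events of the same kind are adjacent in sample order, only the
    more extreme one is kept: the larger ``x`` value for peaks, the smaller
    for troughs (ties keep the earlier index).  Empty inputs pass through.
    """
    v = _values(x)
    peaks = np.asarray(peaks, dtype=int)
    troughs = np.asarray(troughs, dtype=int)
    for arr, name in ((peaks, "peak"), (troughs, "trough")):
        if arr.size and (arr.min() < 0 or arr.max() >= v.size):
            raise InvalidInputError(f"{name} index out of range")
    events = [(int(i), True) for i in peaks] + [(int(i), False) for i in troughs]
    events.sort(key=lambda e: (e[0], not e[1]))
    kept: list[tuple[int, bool]] = []
    for i, is_peak in events:
        if kept and kept[-1][1] == is_peak:
            j = kept[-1][0]
            better = v[i] > v[j] if is_peak else v[i] < v[j]
            if better:
                kept[-1] = (i, is_peak)
        else:
            kept.append((i, is_peak))
    new_peaks = np.array([i for i, p in kept if p], dtype=int)
    new_troughs = np.array([i for i, p in kept if not p], dtype=int)
    return new_peaks, new_troughs


def detect_peaks_and_troughs(x: ArrayLike) -> PeakTroughSet:
    """Detect peaks and troughs of a contractility trace.

    Peaks come from :func:`find_peaks_ampd` on the signal, troughs from the
    same detector on the negated raw signal (each branch detrends
    independently), and alternation is then enforced on the raw values.
    """
    v = _values(x)
    peaks, sel_p = find_peaks_ampd(v)
    troughs, sel_t = find_peaks_ampd(-v)
    peaks, troughs = enforce_alternation(peaks, troughs, v)
    return PeakTroughSet(
        peak_indices=peaks,
        trough_indices=troughs,
        scale_peaks=sel_p,
        scale_troughs=sel_t,
    )
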