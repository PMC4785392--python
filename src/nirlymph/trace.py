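"""Uniformly sampled 1-D contractility traces.

A :class:`Trace` is the in-memory form of a contractility plot: vessel inner
diameter in micrometres, or mean fluorescence intensity (MFI) of a region of
interest, sampled at a fixed frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled signal with a frame rate and a time origin.

    Parameters
    ----------
    values : array-like
        Sample values (diameter in um, or intensity in camera units).
    sample_rate : float
        Samples per second; must be finite and positive.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    units: str = field(default="a.u.", compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("trace values must be one-dimensional")
        if v.size < 2:
            raise InvalidInputError("a trace needs at least two samples")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("trace values must all be finite")
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise InvalidInputError("sample_rate must be finite and positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    @property
    def duration(self) -> float:
        """Covered time span in seconds (n / rate, i.e. including the last frame)."""
        return self.values.size / self.sample_rate

    def window(self, t_start: float, t_end: float) -> "Trace":
        """Return the sub-trace with sample times in the half-open [t_start, t_end).

        Raises
        ------
        InvalidInputError
            If the window is empty, reversed, or leaves fewer than 2 samples.
        """
        if not t_end > t_start:
            raise InvalidInputError("window end must exceed window start")
        t = self.times
        mask = (t >= t_start) & (t < t_end)
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            raise InvalidInputError(
                f"window [{t_start}, {t_end}) contains {idx.size} samples"
            )
        return Trace(
            self.values[idx[0] : idx[-1] + 1],
            self.sample_rate,
            t0=float(t[idx[0]]),
            units=self.units,
        )
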