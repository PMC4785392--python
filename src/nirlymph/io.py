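"""Readers, writers and run configuration.

File conventions: multi-page grayscale TIFF in; CSV (comma separator, ``.``
decimal, UTF-8, LF endings) and JSON out.  Frame rate and pixel scale always
come from configuration, never silently from TIFF tags — acquisition-software
tags are unreliable; a conflicting tag only triggers a warning.  All numeric
CSV columns carry units in their header names.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import FormatError, InvalidInputError
from .metrics import ContractilitySummary, CycleMeasurement, TreatmentEffect
from .trace import Trace

#: Relative tolerance on sample-spacing uniformity when reading traces.
SPACING_RTOL = 1e-6


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page grayscale TIFF as a (frames, rows, cols) array.

    Bit depth is preserved.  RGB/multi-sample TIFFs are rejected; a
    single-page file becomes a stack of one frame (downstream trackers will
    reject it if too short).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            if "S" in axes or series.shape[-1] in (3, 4) and axes.endswith("S"):
                raise FormatError(f"{path} is not grayscale (axes {axes!r})")
            data = series.asarray()
    except FormatError:
        raise
    except Exception as exc:  # unreadable / unsupported compression
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 2-D page series, got shape {data.shape}"
        )
    meta = {"pages": int(data.shape[0]), "dtype": str(data.dtype), "axes": axes}
    return data, meta


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a grayscale image stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_trace_csv(path: str | Path) -> Trace:
    """Read a ``time_s,value`` CSV into a :class:`Trace`.

    The sample rate is inferred from the median spacing; non-monotonic or
    non-uniform (beyond 1e-6 relative) time columns are rejected, as are
    traces too short to analyse (< 10 rows).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(t) & np.isfinite(v)))
    if bad.size:
        raise FormatError(f"{path}: non-numeric row at line {bad[0] + 2}")
    if t.size < 10:
        raise FormatError(f"{path}: at least 10 samples required, got {t.size}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.flatnonzero(dt <= 0)[0])
        raise FormatError(f"{path}: time not strictly increasing at line {i + 3}")
    med = float(np.median(dt))
    if (dt.max() - dt.min()) > SPACING_RTOL * med + 1e-12:
        raise FormatError(f"{path}: sample spacing not uniform within tolerance")
    return Trace(v, sample_rate=1.0 / med, t0=float(t[0]))


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Write a trace as ``time_s,value`` with full round-trip precision."""
    df = pd.DataFrame({"time_s": trace.times, "value": trace.values})
    df.to_csv(path, index=False, lineterminator="\n")


def cycles_table(cycles: list[CycleMeasurement], sample_rate: float, t0: float = 0.0) -> pd.DataFrame:
    """Per-cycle table with times in seconds and raw trace values."""
    rows = [
        {
            "cycle": i,
            "peak_t_s": t0 + c.peak_index / sample_rate,
            "trough_t_s": t0 + c.trough_index / sample_rate,
            "peak_val": c.peak_value,
            "trough_val": c.trough_value,
            "local_mean": c.local_mean,
            "pct_amp": c.pct_amplitude,
        }
        for i, c in enumerate(cycles)
    ]
    return pd.DataFrame(
        rows,
        columns=["cycle", "peak_t_s", "trough_t_s", "peak_val", "trough_val", "local_mean", "pct_amp"],
    )


def summary_table(summaries: dict[str, ContractilitySummary]) -> pd.DataFrame:
    """One row per labelled trace/window summary."""
    rows = []
    for label, s in summaries.items():
        rows.append(
            {
                "trace": label,
                "window_start_s": s.window[0],
                "window_end_s": s.window[1],
                "frequency_per_min": s.frequency,
                "pct_amplitude": s.pct_amplitude,
                "pumping_score": s.pumping_score,
                "mean_level": s.mean_level,
                "n_cycles": s.n_cycles,
                "amplitude_undefined": int(np.isnan(s.pct_amplitude)),
            }
        )
    return pd.DataFrame(rows)


def treatment_table(effect: TreatmentEffect) -> pd.DataFrame:
    """Long-format treatment comparison: metric, baseline, post, % of baseline."""
    b, p = effect.baseline, effect.post
    rows = [
        ("frequency_per_min", b.frequency, p.frequency, effect.frequency_pct),
        ("pct_amplitude", b.pct_amplitude, p.pct_amplitude, effect.amplitude_pct),
        ("pumping_score", b.pumping_score, p.pumping_score, effect.pumping_pct),
        ("tone_mean_level", b.mean_level, p.mean_level, effect.tone_pct),
    ]
    return pd.DataFrame(rows, columns=["metric", "baseline", "post", "pct_of_baseline"])


@dataclass
class AnalysisConfig:
    """Configuration of one tracking/quantification run.

    Windows are ``(start_s, end_s)`` pairs; the defaults follow the 8-minute
    treatment design (baseline 0-2 min, post 3-6 min).
    """

    stack: str | None = None
    frame_rate: float = 2.5
    scale: float = 1.0
    center_x: float | None = None
    center_y: float | None = None
    normal_angle_deg: float = -90.0
    radius_px: float | None = None
    baseline_window: tuple[float, float] = (0.0, 120.0)
    post_window: tuple[float, float] = (180.0, 360.0)
    amplitude_mode: str = "per_cycle"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.scale <= 0:
            raise InvalidInputError("frame_rate and scale must be positive")
        for name in ("baseline_window", "post_window"):
            w = tuple(float(x) for x in getattr(self, name))
            if len(w) != 2 or not w[1] > w[0]:
                raise InvalidInputError(f"{name} must be (start, end) with end > start")
            setattr(self, name, w)
        b, p = self.baseline_window, self.post_window
        if max(b[0], p[0]) < min(b[1], p[1]):
            raise InvalidInputError("baseline and post windows must not overlap")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("baseline_window", "post_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        d["post_window"] = list(self.post_window)
        return d


def check_tiff_tags(meta: dict, frame_rate: float, scale: float) -> None:
    """Warn (never override) when TIFF metadata disagrees with the config."""
    tag_rate = meta.get("frame_rate")
    if tag_rate and abs(tag_rate - frame_rate) > 1e-6 * frame_rate:
        warnings.warn(
            f"TIFF reports {tag_rate} frames/s but config says {frame_rate}; "
            "using the configured value",
            stacklevel=2,
        )
    tag_scale = meta.get("scale")
    if tag_scale and abs(tag_scale - scale) > 1e-6 * scale:
        warnings.warn(
            f"TIFF reports {tag_scale} um/px but config says {scale}; "
            "using the configured value",
            stacklevel=2,
        )


def write_outputs(
    outdir: str | Path,
    summaries: dict[str, ContractilitySummary],
    cycles: dict[str, list[CycleMeasurement]] | None = None,
    sample_rates: dict[str, float] | None = None,
    treatment: TreatmentEffect | None = None,
    config: dict | None = None,
    seed: int | None = None,
    timestamp: str | None = None,
) -> list[Path]:
    """Write summary/cycle/treatment CSVs and a JSON run manifest.

    CSV content is deterministic for identical inputs; the wall-clock
    timestamp lives only in the manifest.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InvalidInputError(f"cannot create output directory {outdir}: {exc}") from exc
    written: list[Path] = []

    p = outdir / "summary.csv"
    summary_table(summaries).to_csv(p, index=False, lineterminator="\n")
    written.append(p)

    if cycles is not None:
        frames = []
        for label, cyc in cycles.items():
            rate = (sample_rates or {}).get(label, 1.0)
            df = cycles_table(cyc, rate)
            df.insert(0, "trace", label)
            frames.append(df)
        all_cycles = (
            pd.concat(frames, ignore_index=True)
            if frames
            else cycles_table([], 1.0).assign(trace=[])
        )
        p = outdir / "cycles.csv"
        all_cycles.to_csv(p, index=False, lineterminator="\n")
        written.append(p)

    if treatment is not None:
        p = outdir / "treatment.csv"
        treatment_table(treatment).to_csv(p, index=False, lineterminator="\n")
        written.append(p)

    manifest = {
        "software": "nirlymph",
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "outputs": [w.name for w in written],
        "timestamp": timestamp,
    }
    p = outdir / "manifest.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
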