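"""NIR diameter tracking with a per-frame moving threshold.

The tracker reproduces a simple, manual-ROI workflow.  Two circular ROIs are
placed on each frame: one of radius r over the vessel centreline, and a
background ROI of radius r/2 whose centre sits at distance 2r from the vessel
centre along the perpendicular direction.  The per-frame ("moving")
threshold is the vessel ROI mean divided by the background ROI mean, which
adapts to tracer washout and contraction-driven brightness changes.

A measurement line runs from the background ROI centre through the vessel
centre to the far edge of the vessel ROI (length 3r).  Each frame's intensity
profile along that line is normalised to the mean of its first ten samples
(local background) and every sample strictly above the threshold is counted
as lumen; the count times the pixel scale is the inner diameter.

Raster conventions (bit-reproducible): coordinates are 0-based ``(x, y)``
with x rightward (columns) and y downward (rows); a disc contains a pixel iff
the pixel centre is within (<=) the radius; line profiles use bilinear
interpolation at unit-pixel spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import InvalidGeometryError, InvalidInputError, ProcessingError
from .trace import Trace

#: Number of leading line-profile samples averaged into the profile
#: normaliser (the local background level).
N_BACKGROUND_PIXELS = 10

#: Abort tracking when more than this fraction of frames fails.
MAX_FAILED_FRACTION = 0.10


@dataclass(frozen=True)
class VesselGeometry:
    """Manual ROI geometry for one vessel.

    Parameters
    ----------
    center : (float, float)
        Vessel centreline point, pixel coordinates (x, y).
    normal : (float, float)
        Direction perpendicular to the vessel axis; normalised on
        construction.  The background ROI lies at ``center + 2r * normal``.
    r : float
        Vessel ROI radius in pixels (>= 3).
    scale : float
        Micrometres per pixel (> 0).
    """

    center: tuple[float, float]
    normal: tuple[float, float]
    r: float
    scale: float

    def __post_init__(self) -> None:
        if self.r < 3:
            raise InvalidGeometryError("vessel ROI radius must be >= 3 px")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise InvalidInputError("scale (um/pixel) must be positive")
        nx, ny = self.normal
        norm = math.hypot(nx, ny)
        if not (np.isfinite(norm) and norm > 0):
            raise InvalidGeometryError("normal direction must be non-zero")
        object.__setattr__(self, "normal", (nx / norm, ny / norm))
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def background_center(self) -> tuple[float, float]:
        cx, cy = self.center
        nx, ny = self.normal
        return (cx + 2 * self.r * nx, cy + 2 * self.r * ny)

    @property
    def background_radius(self) -> float:
        return 0.5 * self.r

    @property
    def line_start(self) -> tuple[float, float]:
        return self.background_center

    @property
    def line_end(self) -> tuple[float, float]:
        cx, cy = self.center
        nx, ny = self.normal
        return (cx - self.r * nx, cy - self.r * ny)

    @property
    def line_length(self) -> float:
        return 3.0 * self.r

    @property
    def n_line_samples(self) -> int:
        return int(round(self.line_length)) + 1

    @classmethod
    def from_angle(
        cls, center: tuple[float, float], normal_angle_deg: float, r: float, scale: float
    ) -> "VesselGeometry":
        """Build a geometry from a normal direction given in degrees
        (0 deg = +x, measured toward +y, i.e. clockwise on screen)."""
        a = math.radians(normal_angle_deg)
        return cls(center=center, normal=(math.cos(a), math.sin(a)), r=r, scale=scale)


@dataclass(frozen=True)
class LineProfile:
    """Intensity samples along the measurement line, background end first."""

    samples: np.ndarray
    positions: np.ndarray  # shape (n, 2), pixel (x, y) of each sample


@dataclass
class DiameterTraceResult:
    """Per-frame tracking output.

    Failed frames (non-positive background or normaliser) hold NaN in the
    float columns and -1 in ``pixel_counts``.
    """

    diameters_um: np.ndarray
    pixel_counts: np.ndarray
    thresholds: np.ndarray
    vessel_mfi: np.ndarray
    background_mfi: np.ndarray
    frame_rate: float
    scale: float
    failed_frames: list[int] = field(default_factory=list)

    def to_trace(self, t0: float = 0.0) -> Trace:
        if self.failed_frames:
            raise InvalidInputError(
                f"cannot build a trace: frames {self.failed_frames} failed"
            )
        return Trace(self.diameters_um, self.frame_rate, t0=t0, units="um")

    def table(self) -> pd.DataFrame:
        n = self.diameters_um.size
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": np.arange(n) / self.frame_rate,
                "diameter_um": self.diameters_um,
                "pixel_count": self.pixel_counts,
                "threshold": self.thresholds,
                "vessel_mfi": self.vessel_mfi,
                "background_mfi": self.background_mfi,
            }
        )


def _disc_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of pixels whose centres lie within the disc."""
    h, w = shape
    cx, cy = center
    if radius <= 0:
        raise InvalidGeometryError("disc radius must be positive")
    y0 = max(0, int(math.floor(cy - radius)))
    y1 = min(h - 1, int(math.ceil(cy + radius)))
    x0 = max(0, int(math.floor(cx - radius)))
    x1 = min(w - 1, int(math.ceil(cx + radius)))
    if y0 > y1 or x0 > x1:
        raise InvalidGeometryError("disc lies fully outside the frame")
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    if not inside.any():
        raise InvalidGeometryError("disc contains no pixel centres")
    return yy[inside], xx[inside]


def disc_mean(frame: np.ndarray, center: tuple[float, float], radius: float) -> float:
    """Mean intensity over pixels whose centres lie within the disc."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidInputError("frame must be a 2-D grayscale image")
    rows, cols = _disc_mask(frame.shape, center, radius)
    return float(frame[rows, cols].mean())


def _line_coordinates(geometry: VesselGeometry) -> np.ndarray:
    """(n, 2) array of (x, y) sample positions at unit-pixel spacing."""
    x0, y0 = geometry.line_start
    x1, y1 = geometry.line_end
    n = geometry.n_line_samples
    length = geometry.line_length
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    j = np.arange(n, dtype=float)
    return np.column_stack([x0 + j * ux, y0 + j * uy])


def sample_line_profile(frame: np.ndarray, geometry: VesselGeometry) -> LineProfile:
    """Bilinearly sampled intensity profile along the measurement line.

    Ordered from the background ROI centre toward the vessel's far edge.
    Raises :class:`InvalidGeometryError` if any sample falls outside the
    frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidInputError("frame must be a 2-D grayscale image")
    pos = _line_coordinates(geometry)
    h, w = frame.shape
    x, y = pos[:, 0], pos[:, 1]
    if x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1:
        raise InvalidGeometryError("measurement line exits the frame")
    samples = map_coordinates(frame, [y, x], order=1, mode="nearest")
    return LineProfile(samples=samples, positions=pos)


def moving_threshold(vessel_mfi: float, background_mfi: float) -> float:
    """Per-frame threshold: vessel ROI mean / background ROI mean."""
    if not (np.isfinite(background_mfi) and background_mfi > 0):
        raise InvalidInputError("background mean intensity must be positive")
    return float(vessel_mfi) / float(background_mfi)


def profile_to_diameter(
    profile: LineProfile | np.ndarray,
    threshold: float,
    scale: float,
    mode: str = "count",
) -> tuple[int, float]:
    """Count supra-threshold samples along the line and convert to um.

    Each sample is normalised by the mean of the first ten samples of the
    same profile; samples strictly above the threshold count as lumen
    (ties are excluded).  The default ``mode="count"`` counts all
    supra-threshold samples without a contiguity requirement;
    ``mode="contiguous"`` instead measures the longest contiguous
    supra-threshold run (a robustness option for noisy acquisitions).
    Returns ``(pixel_count, diameter_um)``.
    """
    samples = profile.samples if isinstance(profile, LineProfile) else np.asarray(profile, dtype=float)
    if mode not in ("count", "contiguous"):
        raise InvalidInputError(f"unknown counting mode {mode!r}")
    if samples.size < N_BACKGROUND_PIXELS:
        raise InvalidInputError(
            f"profile needs at least {N_BACKGROUND_PIXELS} samples to normalise"
        )
    norm = float(samples[:N_BACKGROUND_PIXELS].mean())
    if norm <= 0:
        raise InvalidInputError("profile background normaliser must be positive")
    above = samples / norm > threshold
    if mode == "count":
        count = int(np.count_nonzero(above))
    else:
        count = best = 0
        for flag in above:
            best = best + 1 if flag else 0
            count = max(count, best)
    return count, count * scale


def track_diameter(
    stack: np.ndarray,
    geometry: VesselGeometry,
    frame_rate: float,
    mode: str = "count",
) -> DiameterTraceResult:
    """Track the vessel inner diameter across a grayscale image stack.

    Per frame: ROI means -> moving threshold -> line profile -> pixel
    count -> diameter (``mode`` as in :func:`profile_to_diameter`).  Frames
    with a non-positive background mean or profile normaliser are recorded
    as failed (NaN); more than 10% failed frames aborts with
    :class:`ProcessingError`.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidInputError("stack must be 3-D (frames, rows, columns)")
    if not (np.isfinite(frame_rate) and frame_rate > 0):
        raise InvalidInputError("frame rate must be positive")
    n_frames, h, w = stack.shape
    shape = (h, w)
    # geometry is frame-independent: resolve masks and line once
    v_rows, v_cols = _disc_mask(shape, geometry.center, geometry.r)
    b_rows, b_cols = _disc_mask(shape, geometry.background_center, geometry.background_radius)
    pos = _line_coordinates(geometry)
    x, y = pos[:, 0], pos[:, 1]
    if x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1:
        raise InvalidGeometryError("measurement line exits the frame")

    diameters = np.full(n_frames, np.nan)
    counts = np.full(n_frames, -1, dtype=int)
    thresholds = np.full(n_frames, np.nan)
    vessel = np.full(n_frames, np.nan)
    background = np.full(n_frames, np.nan)
    failed: list[int] = []
    for t in range(n_frames):
        frame = np.asarray(stack[t], dtype=float)
        v_mfi = float(frame[v_rows, v_cols].mean())
        b_mfi = float(frame[b_rows, b_cols].mean())
        vessel[t] = v_mfi
        background[t] = b_mfi
        try:
            thr = moving_threshold(v_mfi, b_mfi)
            samples = map_coordinates(frame, [y, x], order=1, mode="nearest")
            count, diam = profile_to_diameter(samples, thr, geometry.scale, mode=mode)
        except InvalidInputError:
            failed.append(t)
            continue
        thresholds[t] = thr
        counts[t] = count
        diameters[t] = diam
    if len(failed) > MAX_FAILED_FRACTION * n_frames:
        raise ProcessingError(
            f"{len(failed)}/{n_frames} frames failed tracking (frames {failed[:10]}...)"
        )
    return DiameterTraceResult(
        diameters_um=diameters,
        pixel_counts=counts,
        thresholds=thresholds,
        vessel_mfi=vessel,
        background_mfi=background,
        frame_rate=frame_rate,
        scale=geometry.scale,
        failed_frames=failed,
    )


def extract_mfi_trace(
    stack: np.ndarray,
    center: tuple[float, float],
    radius: float,
    frame_rate: float,
    background: tuple[tuple[float, float], float] | None = None,
    t0: float = 0.0,
) -> Trace:
    """Per-frame mean fluorescence intensity of a circular ROI as a Trace.

    ``background`` is an optional ``((x, y), radius)`` disc whose per-frame
    mean is subtracted (background-corrected MFI, the volume proxy).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidInputError("stack must be 3-D (frames, rows, columns)")
    if not (np.isfinite(frame_rate) and frame_rate > 0):
        raise InvalidInputError("frame rate must be positive")
    shape = stack.shape[1:]
    rows, cols = _disc_mask(shape, center, radius)
    values = stack[:, rows, cols].mean(axis=1).astype(float)
    if background is not None:
        b_center, b_radius = background
        b_rows, b_cols = _disc_mask(shape, b_center, b_radius)
        values = values - stack[:, b_rows, b_cols].mean(axis=1).astype(float)
    return Trace(values, frame_rate, t0=t0, units="a.u.")


def vessel_roi_radius(
    d_max_px: float,
    bias_px: float = 0.4,
    noise_fraction: float = 0.0,
    z_margin: float = 3.7,
) -> int:
    """Vessel ROI radius balancing geometric bias against noise robustness.

    On an ideal tracer-filled cylinder the line profile is the chord (path
    length) function and the moving threshold equals the *mean* path over the
    vessel ROI, pbar ~= D^2/(2r) pixels (r >> D/2).  Thresholding the chord
    at pbar under-measures the width by about pbar^2/(2D) = D^3/(8 r^2)
    pixels, so a target bias b requires r >= sqrt(D^3 / (8 b)): a larger ROI
    averages more surrounding background into the vessel mean, lowering the
    threshold toward the background level where the profile edge is steep.

    With per-pixel noise, however, the threshold must also stay several noise
    standard deviations above the background, or the unordered pixel count
    picks up spurious samples along the ~3r background stretch of the line.
    For noise sigma = ``noise_fraction`` x lumen contrast (brightness x D),
    the threshold z-score is z ~= pbar / (noise_fraction * D) =
    D / (2 r * noise_fraction), so keeping z >= ``z_margin`` (with ~10%
    allowance for normaliser noise) caps r at
    D / (2.2 * noise_fraction * z_margin).  The returned radius is the bias
    target clipped to that cap (and never below 3 px or D/2).
    """
    if d_max_px <= 0 or bias_px <= 0:
        raise InvalidInputError("diameter and bias must be positive")
    r = math.sqrt(d_max_px**3 / (8.0 * bias_px))
    if noise_fraction > 0:
        r = min(r, d_max_px / (2.2 * noise_fraction * z_margin))
    r = max(3.0, d_max_px / 2.0 + 1.0, r)
    return int(math.ceil(r))


def suggest_normal(frame: np.ndarray, center: tuple[float, float], half_size: int = 10) -> tuple[float, float]:
    """Suggest a vessel-perpendicular direction from the local intensity ridge.

    Uses the dominant eigenvector of the gradient structure tensor in a
    square patch around ``center``: intensity varies fastest across the
    vessel, so the dominant gradient direction approximates the normal.
    Purely advisory — never overrides a user-supplied geometry.
    """
    frame = np.asarray(frame, dtype=float)
    cx, cy = int(round(center[0])), int(round(center[1]))
    h, w = frame.shape
    y0, y1 = max(0, cy - half_size), min(h, cy + half_size + 1)
    x0, x1 = max(0, cx - half_size), min(w, cx + half_size + 1)
    patch = frame[y0:y1, x0:x1]
    if patch.shape[0] < 3 or patch.shape[1] < 3:
        raise InvalidGeometryError("patch around center too small for a normal estimate")
    gy, gx = np.gradient(patch)
    tensor = np.array(
        [[np.sum(gx * gx), np.sum(gx * gy)], [np.sum(gx * gy), np.sum(gy * gy)]]
    )
    eigvals, eigvecs = np.linalg.eigh(tensor)
    nx, ny = eigvecs[:, int(np.argmax(eigvals))]
    if ny > 0 or (ny == 0 and nx < 0):  # deterministic sign: point "up" (-y)
        nx, ny = -nx, -ny
    return float(nx), float(ny)
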