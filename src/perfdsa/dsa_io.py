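"""Reading, writing and preprocessing of 2D+time angiography series.

A digital subtraction angiography (DSA) acquisition is a time-ordered stack
of 2D frames in which contrast-filled vessels appear dark on a bright
background.  This module provides the :class:`DSASeries` container, readers
for multi-page TIFF stacks and multi-frame DICOM XA files, the spatial
preprocessing used by the pipeline (bilinear resize to a common grid and
per-series min-max intensity normalization to [0, 1]), uniform temporal
resampling, and the minimum-intensity projection (MinIP) that collapses a
series into a single vessel image.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

logger = logging.getLogger(__name__)


class View(enum.Enum):
    """Acquisition projection of a DSA series."""

    AP = "AP"
    LATERAL = "lateral"
    UNKNOWN = "unknown"


@dataclass
class DSASeries:
    """A time-ordered stack of 2D frames with a uniform frame rate.

    Parameters
    ----------
    frames
        ``(T, H, W)`` float array of intensities in ``[0, 1]``.
    frame_rate_hz
        Frames per second; the frame at index ``t`` is acquired at time
        ``t / frame_rate_hz`` seconds (first frame at t = 0).
    view
        Acquisition projection (anteroposterior, lateral, or unknown).
    meta
        Free-form provenance mapping (source path, original dtype range, ...).
    """

    frames: np.ndarray
    frame_rate_hz: float
    view: View = View.UNKNOWN
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a DSA series needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]; normalize first")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape of each frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, seconds, starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate_hz


def _scale_to_unit(stack: np.ndarray) -> tuple[np.ndarray, dict[str, Any]]:
    """Scale an integer/float stack to [0, 1] by its dtype range."""
    meta: dict[str, Any] = {"source_dtype": str(stack.dtype)}
    if np.issubdtype(stack.dtype, np.integer):
        lo = np.iinfo(stack.dtype).min
        hi = np.iinfo(stack.dtype).max
        meta["source_range"] = (int(lo), int(hi))
        out = (stack.astype(np.float64) - lo) / (hi - lo)
    else:
        out = stack.astype(np.float64)
        meta["source_range"] = (float(out.min()), float(out.max()))
        if out.max() > 1 + 1e-9 or out.min() < -1e-9:
            # float stack outside [0,1]: min-max scale
            rng = out.max() - out.min()
            out = (out - out.min()) / rng if rng > 0 else np.zeros_like(out)
    return out, meta


def load_series(
    path: str | Path,
    frame_rate_hz: float | None = None,
    view: View = View.UNKNOWN,
    format_hint: str | None = None,
) -> DSASeries:
    """Load a DSA series from a multi-page TIFF or multi-frame DICOM XA file.

    Parameters
    ----------
    path
        Path to the file.  Format is inferred from the suffix unless
        ``format_hint`` (``"tiff"`` or ``"dicom"``) is given.
    frame_rate_hz
        Override for the frame rate.  Required for TIFF (which carries no
        timing metadata) and for DICOM files missing CineRate/FrameTime.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hint = (format_hint or path.suffix.lstrip(".")).lower()
    if hint in ("dcm", "dicom", "ima"):
        stack, fps_from_meta, meta = _read_dicom_stack(path)
    elif hint in ("tif", "tiff"):
        import tifffile

        stack = tifffile.imread(str(path))
        fps_from_meta = None
        meta = {"source": str(path), "format": "tiff"}
    else:
        raise ValueError(f"unsupported series format: {path.suffix!r}")

    stack = np.asarray(stack)
    if stack.ndim == 2:
        raise ValueError(f"{path} holds a single frame; a series needs T >= 2 frames")
    fps = frame_rate_hz if frame_rate_hz is not None else fps_from_meta
    if fps is None:
        raise ValueError(
            f"{path}: frame rate not found in metadata; pass frame_rate_hz explicitly"
        )
    frames, scale_meta = _scale_to_unit(stack)
    meta.update(scale_meta)
    return DSASeries(frames=frames, frame_rate_hz=float(fps), view=view, meta=meta)


def _read_dicom_stack(path: Path) -> tuple[np.ndarray, float | None, dict[str, Any]]:
    """Read a multi-frame DICOM XA file; return (stack, fps-or-None, meta)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    stack = ds.pixel_array
    fps: float | None = None
    if getattr(ds, "CineRate", None):
        fps = float(ds.CineRate)
    elif getattr(ds, "FrameTime", None):  # milliseconds per frame
        ft = float(ds.FrameTime)
        if ft > 0:
            fps = 1000.0 / ft
    meta = {
        "source": str(path),
        "format": "dicom",
        "modality": str(getattr(ds, "Modality", "")),
    }
    return stack, fps, meta


def save_series(series: DSASeries, path: str | Path) -> None:
    """Write a series as a float32 multi-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), series.frames.astype(np.float32))


def load_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a binary mask from a single-page PNG/TIFF; nonzero = foreground."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:  # RGB(A): any channel nonzero
        arr = arr.max(axis=-1)
    mask = (arr > 0).astype(np.uint8)
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(f"mask shape {mask.shape} != expected {tuple(expected_shape)}")
    return mask


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG/TIFF (255 = foreground)."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def normalize_and_resize(series: DSASeries, target_h: int, target_w: int) -> DSASeries:
    """Resize every frame bilinearly and min-max normalize the series to [0, 1].

    Normalization is per-series (a single min/max over all frames), which
    preserves the relative temporal contrast dynamics that the time-intensity
    curves downstream depend on.  A constant series cannot be normalized and
    maps to all zeros with a warning.
    """
    if target_h <= 0 or target_w <= 0:
        raise ValueError("target dimensions must be positive")
    from skimage.transform import resize

    T = series.n_frames
    if series.shape == (target_h, target_w):
        resized = series.frames.copy()
    else:
        resized = np.empty((T, target_h, target_w), dtype=np.float64)
        for t in range(T):
            resized[t] = resize(
                series.frames[t], (target_h, target_w), order=1,
                mode="edge", anti_aliasing=False, preserve_range=True,
            )
    lo, hi = resized.min(), resized.max()
    if hi - lo <= 0:
        warnings.warn("constant series: normalization maps all intensities to 0")
        out = np.zeros_like(resized)
    else:
        out = (resized - lo) / (hi - lo)
    meta = dict(series.meta, normalized="per-series min-max")
    return DSASeries(np.clip(out, 0.0, 1.0), series.frame_rate_hz, series.view, meta)


def resize_mask(mask: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Resize a binary mask with nearest-neighbor interpolation (stays binary)."""
    from skimage.transform import resize

    out = resize(
        np.asarray(mask, dtype=np.float64), (target_h, target_w),
        order=0, mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return (out > 0.5).astype(np.uint8)


def minip(series: DSASeries) -> np.ndarray:
    """Minimum-intensity projection across the time axis.

    Pixel ``(i, j)`` of the output is ``min_t frames[t, i, j]``; vessels,
    being dark in subtraction angiography, are darkest in the projection.
    """
    return series.frames.min(axis=0)


def resample_temporal(series: DSASeries, target_fps: float) -> DSASeries:
    """Linearly resample every pixel's time course onto a uniform grid.

    The new grid spans the original time range ``[0, (T-1)/fps]`` at
    ``target_fps`` samples per second, including both endpoints' neighborhood;
    resampling at the native frame rate is the identity.
    """
    if target_fps <= 0:
        raise ValueError("target_fps must be positive")
    t_old = series.times
    duration = t_old[-1]
    n_new = int(np.floor(duration * target_fps)) + 1
    if n_new < 2:
        raise ValueError("target grid would have fewer than 2 samples")
    t_new = np.arange(n_new) / target_fps
    T, H, W = series.frames.shape
    flat = series.frames.reshape(T, H * W)
    # np.interp per column via vectorized index arithmetic
    idx = np.clip(np.searchsorted(t_old, t_new, side="right") - 1, 0, T - 2)
    frac = (t_new - t_old[idx]) / (t_old[idx + 1] - t_old[idx])
    out = (1 - frac)[:, None] * flat[idx] + frac[:, None] * flat[idx + 1]
    meta = dict(series.meta, resampled_from_hz=series.frame_rate_hz)
    return DSASeries(
        np.clip(out.reshape(n_new, H, W), 0.0, 1.0),
        float(target_fps), series.view, meta,
    )
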