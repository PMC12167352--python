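"""Time-intensity curves and arterial input function extraction.

Subtraction angiography renders contrast dark on bright, so per-pixel
contrast concentration is recovered as the intensity *drop* relative to a
baseline — by default the pixel's first-frame (pre-contrast) intensity,
floored at zero.  The arterial input function (AIF) is the average
concentration curve over all pixels of the segmented input artery, here the
supraclinoid segment of the internal carotid artery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .dsa_io import DSASeries


@dataclass
class TIC:
    """A per-pixel time-concentration curve on a uniform grid."""

    times: np.ndarray  # seconds
    values: np.ndarray  # relative concentration, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) < 2:
            raise ValueError("a curve needs at least 2 samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if steps[0] <= 0:
            raise ValueError("time grid must be increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class AIFCurve(TIC):
    """Arterial input function: an averaged TIC plus mask provenance."""

    source: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.min() < 0:
            raise ValueError("AIF values must be non-negative")
        if not np.any(self.values > 0):
            raise ValueError("AIF has no strictly positive value")


def to_concentration(series: DSASeries, baseline: str | float = "first-frame") -> np.ndarray:
    """Convert a series in [0, 1] to a non-negative concentration stack.

    ``c[t, i, j] = max(0, baseline[i, j] - I[t, i, j])``.  ``baseline`` is
    either ``"first-frame"`` (per-pixel intensity of frame 0, the natural
    choice for subtracted series whose first frame is pre-contrast) or a
    fixed scalar such as 1.0.
    """
    if baseline == "first-frame":
        base = series.frames[0]
    else:
        base = float(baseline) * np.ones(series.shape)
    return np.maximum(0.0, base[None, :, :] - series.frames)


def extract_tic(series: DSASeries, pixel: tuple[int, int], baseline: str | float = "first-frame") -> TIC:
    """Concentration curve of a single pixel, on the series' frame-time grid."""
    i, j = pixel
    H, W = series.shape
    if not (0 <= i < H and 0 <= j < W):
        raise IndexError(f"pixel {pixel} out of bounds for {H}x{W} frames")
    conc = to_concentration(series, baseline=baseline)
    return TIC(series.times, conc[:, i, j])


def average_aif(
    series: DSASeries, ia_mask: np.ndarray, baseline: str | float = "first-frame"
) -> AIFCurve:
    """Arterial input function as the mean TIC over all input-artery pixels."""
    mask = np.asarray(ia_mask) > 0
    if mask.shape != series.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {series.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no input-artery pixels: the IA mask is empty")
    conc = to_concentration(series, baseline=baseline)
    values = conc[:, mask].mean(axis=1)
    return AIFCurve(series.times, values, source={"n_pixels": n, "baseline": baseline})


def aif_similarity(a: TIC, b: TIC) -> dict[str, float | None]:
    """Root-mean-square error and Pearson correlation of two curves.

    RMSE is reported on the normalized [0, 1] intensity scale.  The Pearson
    coefficient is undefined (``None``) when either curve is constant.
    """
    if len(a.values) != len(b.values):
        raise ValueError("curves must share the grid length")
    x, y = a.values, b.values
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    if np.std(x) == 0 or np.std(y) == 0:
        pcc = None
    else:
        pcc = float(np.corrcoef(x, y)[0, 1])
    return {"rmse": rmse, "pcc": pcc}
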