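"""Color-coded rendering of perfusion maps and region summary statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deconv import ParametricMaps


@dataclass
class RegionSummary:
    """Mean perfusion parameters over the valid pixels of one territory."""

    region_name: str
    mean_cbv: float
    mean_cbf: float
    mean_mtt: float
    mean_tmax: float
    n_pixels: int


def robust_range(map2d: np.ndarray, valid_mask: np.ndarray | None = None,
                 percentiles: tuple[float, float] = (2.0, 98.0)) -> tuple[float, float]:
    """Default display range: robust percentiles of the valid pixels."""
    vals = map2d if valid_mask is None else map2d[np.asarray(valid_mask) > 0]
    if vals.size == 0:
        return 0.0, 1.0
    lo, hi = np.percentile(vals, percentiles)
    if hi <= lo:
        hi = lo + 1e-12
    return float(lo), float(hi)


def colorize(
    map2d: np.ndarray,
    value_range: tuple[float, float],
    colormap_name: str = "inferno",
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Map a parametric image through a perceptually uniform colormap.

    Values are clipped to ``value_range`` and mapped linearly; pixels outside
    ``valid_mask`` are rendered black.  Returns an ``(H, W, 3)`` float RGB
    image in [0, 1].
    """
    lo, hi = value_range
    if not (hi > lo):
        raise ValueError("value_range must satisfy low < high")
    import matplotlib

    cmap = matplotlib.colormaps[colormap_name]
    norm = np.clip((np.asarray(map2d, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.asarray(cmap(norm))[..., :3]
    if valid_mask is not None:
        rgb[np.asarray(valid_mask) == 0] = 0.0
    return rgb


def territory_summary(
    maps: ParametricMaps, region_mask: np.ndarray, name: str
) -> RegionSummary:
    """Average CBV/CBF/MTT/Tmax over a territory's valid pixels.

    The mean is taken over the intersection of ``region_mask`` with the
    maps' valid mask, so excluded (background / zero-flow) pixels never
    influence a territory's summary.
    """
    region = np.asarray(region_mask) > 0
    if region.shape != maps.valid_mask.shape:
        raise ValueError("region mask shape does not match the maps")
    sel = region & (maps.valid_mask > 0)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"territory {name!r} has no valid perfusion pixels")
    return RegionSummary(
        region_name=name,
        mean_cbv=float(maps.cbv_map[sel].mean()),
        mean_cbf=float(maps.cbf_map[sel].mean()),
        mean_mtt=float(maps.mtt_map[sel].mean()),
        mean_tmax=float(maps.tmax_map[sel].mean()),
        n_pixels=n,
    )
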