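"""Synthetic DSA phantoms with known perfusion ground truth.

The generator realizes the indicator-dilution forward model: an input artery
carries a gamma-variate contrast bolus ``C_art(t)``, and each tissue region's
concentration curve is

    C_voi(t) = CBF * rho_voi * (C_art o r)(t)

for a residue function ``r(t)`` with unit maximum (``o`` denotes
convolution).  The exponential and boxcar residue families both have
closed-form parameters: ``max r = 1``, ``integral r dt = MTT``, so the true
relative volume is ``CBV = CBF * MTT`` and the bolus-delay marker ``Tmax``
equals the region's delay.  Concentration is rendered with subtraction-
angiography polarity (contrast darkens the image): ``I = clip(1 - c, 0, 1)``,
background pixels stay at intensity 1, and optional Gaussian noise is added
before clipping.  ``rho_voi`` is fixed to 1 in generation, so all phantom
parameters are in relative units, matching the ratio definition of CBV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from .dsa_io import DSASeries, View

Geometry = dict
ResidueKind = Literal["exponential", "boxcar"]


def gamma_variate(
    t: np.ndarray | float, t0: float, alpha: float, beta: float, amplitude: float
) -> np.ndarray:
    """Peak-normalized gamma-variate bolus curve.

    Zero for ``t <= t0``; for ``t > t0``::

        amplitude * ((t - t0) / (alpha * beta))**alpha * exp(alpha - (t - t0)/beta)

    which attains its maximum, exactly ``amplitude``, at ``t = t0 + alpha*beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma-variate shape (alpha) and scale (beta) must be positive")
    t = np.asarray(t, dtype=np.float64)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    with np.errstate(over="ignore"):
        out[pos] = amplitude * (tau[pos] / (alpha * beta)) ** alpha * np.exp(
            alpha - tau[pos] / beta
        )
    return out


def residue_function(
    kind: ResidueKind, mtt_s: float, delay_s: float = 0.0
) -> Callable[[np.ndarray | float], np.ndarray]:
    """Return a residue function r(t) with max 1 and integral equal to MTT.

    ``exponential``: r(t) = exp(-(t - delay)/MTT) for t >= delay, else 0.
    ``boxcar``:      r(t) = 1 for delay <= t < delay + MTT, else 0.
    """
    if mtt_s <= 0:
        raise ValueError("mtt_s must be positive")
    if delay_s < 0:
        raise ValueError("delay_s must be non-negative")

    if kind == "exponential":

        def r(t):
            t = np.asarray(t, dtype=np.float64)
            tau = t - delay_s
            return np.where(tau >= 0, np.exp(-np.clip(tau, 0, None) / mtt_s), 0.0)

    elif kind == "boxcar":

        def r(t):
            t = np.asarray(t, dtype=np.float64)
            tau = t - delay_s
            return np.where((tau >= 0) & (tau < mtt_s), 1.0, 0.0)

    else:
        raise ValueError(f"unknown residue kind: {kind!r}")

    return r


def forward_tic(
    aif_values: np.ndarray,
    dt: float,
    cbf: float,
    residue: Callable[[np.ndarray], np.ndarray],
    rho: float = 1.0,
) -> np.ndarray:
    """Tissue concentration curve from the indicator-dilution forward model.

    Discrete convolution with grid-spacing scaling, truncated to the grid::

        C_voi[n] = cbf * rho * dt * sum_m C_art[m] * r[(n - m) * dt]
    """
    aif_values = np.asarray(aif_values, dtype=np.float64)
    n = len(aif_values)
    r_samples = residue(np.arange(n) * dt)
    return cbf * rho * dt * np.convolve(aif_values, r_samples)[:n]


@dataclass
class RegionSpec:
    """One perfused tissue region of a phantom."""

    geometry: Geometry  # {"kind": "rect", "row0","col0","row1","col1"} or {"kind": "disk", "row","col","radius"}
    cbf: float  # relative flow, 1/s
    mtt_s: float
    residue_kind: ResidueKind = "exponential"
    delay_s: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.cbf < 0:
            raise ValueError("cbf must be >= 0")
        if self.mtt_s <= 0:
            raise ValueError("mtt_s must be > 0")


@dataclass
class PhantomSpec:
    """Generative description of a synthetic DSA series.

    Defaults model a short cerebral acquisition: 3 frames per second for
    20 s, a gamma-variate arterial bolus arriving after 1 s with a ~2 s
    rise, and a sub-quantization noise floor.  The bolus amplitude is kept
    at 0.4 so intensity clipping never engages, even when the injection
    profile is rescaled by 2x in invariance experiments.
    """

    height: int = 64
    width: int = 64
    frame_rate_hz: float = 3.0
    duration_s: float = 20.0
    aif_t0_s: float = 1.0
    aif_alpha: float = 3.0
    aif_beta_s: float = 0.7
    aif_amplitude: float = 0.4
    ia_geometry: Geometry | None = None
    regions: list[RegionSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s * self.frame_rate_hz < 4:
            raise ValueError("series must contain at least 4 frames")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.frame_rate_hz)) + 1
        return np.arange(n) / self.frame_rate_hz

    def aif(self, times: np.ndarray | None = None) -> np.ndarray:
        t = self.times if times is None else np.asarray(times)
        return gamma_variate(t, self.aif_t0_s, self.aif_alpha, self.aif_beta_s, self.aif_amplitude)


@dataclass
class GroundTruth:
    """True per-pixel perfusion maps and the generating arterial curve."""

    cbv_map: np.ndarray
    cbf_map: np.ndarray
    mtt_map: np.ndarray
    tmax_map: np.ndarray
    ia_mask: np.ndarray
    region_masks: dict[str, np.ndarray]
    aif_times: np.ndarray
    aif_values: np.ndarray


def _rasterize(geom: Geometry, height: int, width: int) -> np.ndarray:
    kind = geom.get("kind", "rect")
    mask = np.zeros((height, width), dtype=bool)
    if kind == "rect":
        r0, c0, r1, c1 = geom["row0"], geom["col0"], geom["row1"], geom["col1"]
        if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
            raise ValueError(f"rect {geom} outside {height}x{width} bounds")
        mask[r0:r1, c0:c1] = True
    elif kind == "disk":
        r, c, rad = geom["row"], geom["col"], geom["radius"]
        if not (0 <= r - rad and r + rad < height and 0 <= c - rad and c + rad < width):
            raise ValueError(f"disk {geom} outside {height}x{width} bounds")
        rr, cc = np.ogrid[:height, :width]
        mask = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
    else:
        raise ValueError(f"unknown geometry kind: {kind!r}")
    return mask


def render(spec: PhantomSpec) -> tuple[DSASeries, GroundTruth]:
    """Render a phantom series and its ground truth.

    Input-artery pixels carry the arterial bolus itself; each region's pixels
    carry the forward-model tissue curve for that region's parameters.
    Raises if any two geometries overlap (the truth would be ambiguous).
    """
    H, W = spec.height, spec.width
    times = spec.times
    T = len(times)
    dt = 1.0 / spec.frame_rate_hz
    aif = spec.aif()

    ia_mask = (
        _rasterize(spec.ia_geometry, H, W)
        if spec.ia_geometry is not None
        else np.zeros((H, W), dtype=bool)
    )
    occupancy = ia_mask.astype(int).copy()
    conc = np.zeros((T, H, W))
    conc[:, ia_mask] = aif[:, None]

    cbv = np.zeros((H, W))
    cbf = np.zeros((H, W))
    mtt = np.zeros((H, W))
    tmax = np.zeros((H, W))
    region_masks: dict[str, np.ndarray] = {}
    for i, reg in enumerate(spec.regions):
        m = _rasterize(reg.geometry, H, W)
        occupancy += m.astype(int)
        r = residue_function(reg.residue_kind, reg.mtt_s, reg.delay_s)
        tic = forward_tic(aif, dt, reg.cbf, r, rho=1.0)
        conc[:, m] = tic[:, None]
        cbf[m] = reg.cbf
        mtt[m] = reg.mtt_s
        cbv[m] = reg.cbf * reg.mtt_s  # CBF * integral of r
        tmax[m] = reg.delay_s
        region_masks[reg.name or f"region{i}"] = m.astype(np.uint8)
    if occupancy.max() > 1:
        raise ValueError("overlapping region/input-artery geometries: truth is ambiguous")

    frames = 1.0 - conc
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0.0, 1.0)

    series = DSASeries(
        frames, spec.frame_rate_hz, View.UNKNOWN,
        meta={"source": "phantom", "seed": spec.seed, "noise_sigma": spec.noise_sigma},
    )
    truth = GroundTruth(
        cbv_map=cbv, cbf_map=cbf, mtt_map=mtt, tmax_map=tmax,
        ia_mask=ia_mask.astype(np.uint8), region_masks=region_masks,
        aif_times=times, aif_values=aif,
    )
    return series, truth


def default_phantom(
    noise_sigma: float = 0.0,
    seed: int = 0,
    frame_rate_hz: float = 4.0,
    duration_s: float = 60.0,
    aif_amplitude: float = 0.4,
) -> PhantomSpec:
    """A two-region phantom: input artery strip plus fast and slow tissue beds."""
    return PhantomSpec(
        height=64,
        width=64,
        frame_rate_hz=frame_rate_hz,
        duration_s=duration_s,
        aif_amplitude=aif_amplitude,
        ia_geometry={"kind": "rect", "row0": 4, "col0": 28, "row1": 24, "col1": 34},
        regions=[
            RegionSpec(
                geometry={"kind": "disk", "row": 40, "col": 16, "radius": 9},
                cbf=0.5, mtt_s=4.0, residue_kind="exponential", delay_s=2.0,
                name="fast_bed",
            ),
            RegionSpec(
                geometry={"kind": "disk", "row": 40, "col": 48, "radius": 9},
                cbf=0.15, mtt_s=8.0, residue_kind="boxcar", delay_s=4.0,
                name="slow_bed",
            ),
        ],
        noise_sigma=noise_sigma,
        seed=seed,
    )


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> None:
    """Render a phantom and write series, masks, truth maps and truth.json."""
    import tifffile

    from .dsa_io import save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth = render(spec)
    tifffile.imwrite(str(out / "series.tiff"), series.frames.astype(np.float32))
    save_mask(truth.ia_mask, out / "ia_mask.png")
    for name, m in truth.region_masks.items():
        save_mask(m, out / f"{name}_mask.png")
    for name in ("cbv", "cbf", "mtt", "tmax"):
        tifffile.imwrite(
            str(out / f"{name}_true.tiff"),
            getattr(truth, f"{name}_map").astype(np.float32),
        )
    info = {
        "frame_rate_hz": spec.frame_rate_hz,
        "duration_s": spec.duration_s,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "aif": {
            "t0_s": spec.aif_t0_s, "alpha": spec.aif_alpha,
            "beta_s": spec.aif_beta_s, "amplitude": spec.aif_amplitude,
        },
        "regions": [
            {
                "name": r.name or f"region{i}", "cbf": r.cbf, "mtt_s": r.mtt_s,
                "residue_kind": r.residue_kind, "delay_s": r.delay_s,
                "cbv": r.cbf * r.mtt_s,
            }
            for i, r in enumerate(spec.regions)
        ],
    }
    (out / "truth.json").write_text(json.dumps(info, indent=2))
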