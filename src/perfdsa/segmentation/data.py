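"""Desk-scale synthetic training data for input-artery segmentation.

Each sample is the minimum-intensity projection (MinIP) of a randomized
rendered phantom: one input-artery strip carrying the full arterial bolus
(the darkest structure), one to three perfused tissue disks that darken
less, and additive Gaussian noise.  The reference mask is the phantom's true
input-artery geometry.  The variability (position, size, orientation by
aspect, bolus amplitude, tissue parameters, noise) stands in for the
anatomical and injection variability of clinical angiograms at a much
smaller scale; see the package methods note for what this does and does not
emulate.
"""

from __future__ import annotations

import numpy as np

from ..dsa_io import minip
from ..phantom import PhantomSpec, RegionSpec, render


def random_phantom_spec(rng: np.random.Generator, size: int = 128) -> PhantomSpec:
    """A randomized single-artery phantom spec for segmentation training."""
    # input-artery strip: elongated rectangle, random position/aspect
    long_side = int(rng.integers(size // 4, size // 2))
    short_side = int(rng.integers(max(3, size // 32), max(5, size // 16)))
    if rng.random() < 0.5:
        h_ia, w_ia = long_side, short_side
    else:
        h_ia, w_ia = short_side, long_side
    r0 = int(rng.integers(2, size - h_ia - 2))
    c0 = int(rng.integers(2, size - w_ia - 2))
    ia = {"kind": "rect", "row0": r0, "col0": c0, "row1": r0 + h_ia, "col1": c0 + w_ia}

    regions = []
    occupied = [(r0, c0, r0 + h_ia, c0 + w_ia)]
    for i in range(int(rng.integers(1, 4))):
        for _ in range(20):  # rejection-sample a non-overlapping disk
            rad = int(rng.integers(size // 16, size // 8))
            rr = int(rng.integers(rad + 1, size - rad - 2))
            cc = int(rng.integers(rad + 1, size - rad - 2))
            box = (rr - rad, cc - rad, rr + rad + 1, cc + rad + 1)
            if all(box[2] <= o[0] or box[0] >= o[2] or box[3] <= o[1] or box[1] >= o[3]
                   for o in occupied):
                occupied.append(box)
                regions.append(RegionSpec(
                    geometry={"kind": "disk", "row": rr, "col": cc, "radius": rad},
                    cbf=float(rng.uniform(0.1, 0.4)),
                    mtt_s=float(rng.uniform(2.0, 8.0)),
                    residue_kind="exponential" if rng.random() < 0.5 else "boxcar",
                    delay_s=float(rng.uniform(0.0, 3.0)),
                ))
                break
    return PhantomSpec(
        height=size, width=size, frame_rate_hz=3.0, duration_s=20.0,
        aif_amplitude=float(rng.uniform(0.3, 0.6)),
        aif_t0_s=float(rng.uniform(0.5, 2.0)),
        ia_geometry=ia, regions=regions,
        noise_sigma=0.01, seed=int(rng.integers(0, 2**31 - 1)),
    )


def minip_mask_dataset(
    n: int, size: int = 128, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render ``n`` randomized phantoms and return (MinIP, IA-mask) pairs."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        series, truth = render(random_phantom_spec(rng, size))
        pairs.append((minip(series).astype(np.float32), truth.ia_mask))
    return pairs
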