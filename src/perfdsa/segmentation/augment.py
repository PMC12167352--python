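"""Paired geometric augmentation for image/mask training samples.

Four transforms, each applied independently with a configurable probability
(0.5 by default): horizontal flip, translation drawn from +/-5% of the image
size, isotropic scaling in 1 +/- 5%, and rotation in +/-10 degrees.  The
identical geometric transform is applied to the image (bilinear) and the
mask (nearest-neighbor, so it stays binary).  The flip is an exact array
reversal; the remaining three compose into a single affine warp about the
image center.
"""

from __future__ import annotations

import numpy as np


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    prob: float = 0.5,
    translate_frac: float = 0.05,
    scale_frac: float = 0.05,
    rotate_deg: float = 10.0,
    hflip: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly transform a paired (image, mask) sample."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share shape")

    if hflip and rng.random() < prob:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    h, w = image.shape
    angle = np.deg2rad(rng.uniform(-rotate_deg, rotate_deg)) if (rotate_deg and rng.random() < prob) else 0.0
    scale = 1.0 + rng.uniform(-scale_frac, scale_frac) if (scale_frac and rng.random() < prob) else 1.0
    if translate_frac and rng.random() < prob:
        ty = rng.uniform(-translate_frac, translate_frac) * h
        tx = rng.uniform(-translate_frac, translate_frac) * w
    else:
        ty = tx = 0.0

    if angle == 0.0 and scale == 1.0 and ty == 0.0 and tx == 0.0:
        return image, mask

    from skimage.transform import AffineTransform, warp

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # forward map in (x, y): p' = s R (p - c) + c + t
    fwd = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(rotation=angle, scale=scale)
        + AffineTransform(translation=(cx + tx, cy + ty))
    )
    img_out = warp(image.astype(np.float64), fwd.inverse, order=1, mode="edge", preserve_range=True)
    mask_out = warp(mask.astype(np.float64), fwd.inverse, order=0, mode="constant", cval=0, preserve_range=True)
    return img_out, (mask_out > 0.5).astype(mask.dtype)


def displacement_bound(
    h: int, w: int, rotate_deg: float, scale_frac: float, translate_frac: float
) -> float:
    """Analytic upper bound on pixel displacement under the augmentation.

    A point at radius ``r`` from the center moves by at most
    ``r * ||s R - I||_2 + |t|`` where ``||s R - I||_2 =
    sqrt(1 + s^2 - 2 s cos(theta))`` at the extreme angle/scale, plus the
    maximal translation magnitude.
    """
    r = np.hypot((h - 1) / 2.0, (w - 1) / 2.0)
    s = 1.0 + scale_frac
    theta = np.deg2rad(rotate_deg)
    rot_scale = np.sqrt(max(1.0 + s**2 - 2.0 * s * np.cos(theta), (s - 1.0) ** 2))
    t = translate_frac * np.hypot(h, w)
    return float(r * rot_scale + t)
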