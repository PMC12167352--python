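import dataclasses

import numpy as np
import pytest

from perfdsa import (
    AIFCurve,
    DeconvConfig,
    average_aif,
    compute_maps,
    default_phantom,
    render,
)

# deconvolution settings for noiseless validation: effectively unregularized
NOISELESS_CONFIG = DeconvConfig(lambda_frac=1e-4)


@pytest.fixture(scope="session")
def phantom_60s():
    """Noiseless two-region phantom at 4 fps for 60 s, with ground truth."""
    spec = default_phantom(frame_rate_hz=4.0, duration_s=60.0)
    series, truth = render(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def phantom_aif(phantom_60s):
    _, series, truth = phantom_60s
    return average_aif(series, truth.ia_mask)


@pytest.fixture(scope="session")
def phantom_maps(phantom_60s):
    _, series, truth = phantom_60s
    return compute_maps(series, truth.ia_mask, NOISELESS_CONFIG)


@pytest.fixture()
def gamma_aif_grid():
    """A short gamma-variate AIF on a coarse grid, for operator tests."""
    from perfdsa import gamma_variate

    t = np.arange(24) * 0.5
    return AIFCurve(t, gamma_variate(t, 1.0, 3.0, 0.7, 0.4))


def region_mean(maps, mask, valid=True):
    sel = np.asarray(mask) > 0
    if valid:
        sel &= maps.valid_mask > 0
    return {name: float(arr[sel].mean()) for name, arr in maps}
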