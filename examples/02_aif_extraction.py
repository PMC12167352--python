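"""Extract the arterial input function and measure its fidelity.

The AIF is the mean time-concentration curve over the input-artery mask
(in clinical use, the segmented supraclinoid internal carotid artery).  On
a noiseless phantom it should reproduce the generating bolus to within
rendering precision.
"""

import numpy as np

from perfdsa import TIC, aif_similarity, average_aif, default_phantom, render

series, truth = render(default_phantom(duration_s=30.0))
aif = average_aif(series, truth.ia_mask)
print(f"AIF averaged over {aif.source['n_pixels']} input-artery pixels")
print(f"peak concentration {aif.values.max():.3f} at t = {aif.times[np.argmax(aif.values)]:.2f} s")

sim = aif_similarity(aif, TIC(truth.aif_times, truth.aif_values))
print(f"against the generating bolus: RMSE = {sim['rmse']:.2e} "
      f"(on the [0,1] intensity scale), Pearson r = {sim['pcc']:.6f}")
# RMSE ~ 1e-16 and r = 1.0: the extraction is exact on noiseless data; with
# noise, averaging over the artery suppresses per-pixel error by ~1/sqrt(n).
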