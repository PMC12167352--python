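"""Render a perfusion phantom and recover its parameters by deconvolution.

Builds a noiseless two-region phantom (an input-artery strip carrying a
gamma-variate bolus, a fast exponential tissue bed and a slow plug-flow
bed), runs the bolus-tracking pipeline and compares the region-mean CBV,
CBF, MTT and Tmax maps against the generating ground truth.
"""

import numpy as np

from perfdsa import DeconvConfig, compute_maps, default_phantom, render

spec = default_phantom(frame_rate_hz=4.0, duration_s=60.0)
series, truth = render(spec)
print(f"phantom: {series.n_frames} frames of {series.shape} at {series.frame_rate_hz} fps")

# noiseless data needs essentially no regularization
maps = compute_maps(series, truth.ia_mask, DeconvConfig(lambda_frac=1e-4))

for reg in spec.regions:
    sel = (truth.region_masks[reg.name] > 0) & (maps.valid_mask > 0)
    print(f"\nregion {reg.name!r} (true cbf={reg.cbf}/s, mtt={reg.mtt_s}s, "
          f"cbv={reg.cbf * reg.mtt_s}, delay={reg.delay_s}s):")
    print(f"  recovered cbf  = {maps.cbf_map[sel].mean():.4f} 1/s")
    print(f"  recovered mtt  = {maps.mtt_map[sel].mean():.4f} s")
    print(f"  recovered cbv  = {maps.cbv_map[sel].mean():.4f}")
    print(f"  recovered tmax = {maps.tmax_map[sel].mean():.4f} s")

# CBF and CBV are in relative units (rho fixed to 1); MTT and Tmax in
# seconds. Small CBV/MTT excess over truth reflects the rectangle-rule bias
# of the sampled convolution (about dt/2 on the residue integral).
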