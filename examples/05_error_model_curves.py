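"""Population FP/FN error curves for uniform and dynamic schemes.

With scan means Normal(M, S) and within-scan SD 30 HU, the uniform-
threshold FP has a Gaussian-convolution closed form, while the dynamic
mean + N.SD scheme is phase-invariant: FP = 1 - Phi(N) everywhere.
"""

import numpy as np

from aohu import PopulationModel, error_curves, make_plaque_law, min_threshold_for_fp
from scipy.stats import norm

law = make_plaque_law()
pops = {
    "delayed": PopulationModel(M=110, S=16, sigma_bar=30, phase="delayed"),
    "venous": PopulationModel(M=180, S=30, sigma_bar=30, phase="venous"),
    "arterial": PopulationModel(M=326, S=68, sigma_bar=30, phase="arterial"),
}

curves = error_curves(law, pops, uniform_grid=[200, 300, 400, 550],
                      dynamic_grid=[2, 3, 4], rng=np.random.default_rng(0))
print(curves.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

T_eq = min_threshold_for_fp(pops["arterial"], float(norm.sf(3)))
print(f"\nuniform threshold matching the dynamic-3SD FP floor (arterial): {T_eq:.0f} HU")
# Reading: dynamic FP is identical across phases (0.13% at N = 3), while
# the uniform scheme needs ~550 HU to reach the same floor in arterial
# scans — at the cost of missing ~85% of plaque pixels.
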