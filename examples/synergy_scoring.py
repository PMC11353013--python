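"""Score a drug-combination checkerboard for Bliss and HSA synergy.

Builds a synthetic 9x9 viability matrix for a panRAF + MEK inhibitor pair
with a localized synergy bump, then runs the smoothing + excess-scoring
analysis the screen uses.
"""

import numpy as np

from combotrans import synth
from combotrans.dose_response import synergy_analysis

doses_a = np.concatenate([[0.0], 10.0 * 10.0 ** (-0.5 * np.arange(8)[::-1])])
doses_b = np.concatenate([[0.0], 5.0 * 10.0 ** (-0.5 * np.arange(8)[::-1])])

matrix, truth = synth.generate_viability_matrix(
    margin_a=(1.0, 0.25, 0.5, 1.5),   # panRAFi: upper, floor, EC50 µM, hill
    margin_b=(1.0, 0.40, 0.08, 1.5),  # MEKi (shallow, NRAS-like)
    doses_a=doses_a, doses_b=doses_b,
    bump={"amplitude": 0.4, "center": (0.3, 0.05), "width": 0.5},
    noise_sd=0.05, seed=7,
    drug_a="belvarafenib", drug_b="cobimetinib", cell_line="NRAS_Q61_demo")

result = synergy_analysis(matrix)
imax = np.unravel_index(np.argmax(result.bliss_excess), result.bliss_excess.shape)

print(f"cell line:      {matrix.cell_line}")
print(f"Bliss score:    {result.bliss_score:.3f}   (mean of top-10% excess; "
      "~0 = additive, >0.2 = strongly synergistic)")
print(f"HSA score:      {result.hsa_score:.3f}")
print(f"peak excess:    {result.bliss_excess[imax]:.3f} at "
      f"{matrix.doses_a[imax[0]]:.3g} µM belvarafenib + "
      f"{matrix.doses_b[imax[1]]:.3g} µM cobimetinib")
print("A positive Bliss excess means the combination inhibits more than")
print("independent drug action predicts at that dose pair.")
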