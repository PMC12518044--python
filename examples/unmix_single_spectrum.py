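"""Decompose one absorbance spectrum into species concentrations.

Builds the band-anchored reference set (Pchlide 651 nm, ES complex
633 nm, Chlide 670 nm), forward-models a mixture with a baseline offset
and noise, and unmixes it back.
"""

import numpy as np

from dporkin.spectra import Spectrum
from dporkin.synth import make_reference_set
from dporkin.unmix import unmix_spectrum

refs, _ = make_reference_set()
grid = refs.common_grid

truth = {"S": 12.0, "ES": 1.2, "P": 3.0}  # uM
rng = np.random.default_rng(0)
absorbance = (refs.eps_S * truth["S"] + refs.eps_ES * truth["ES"]
              + refs.eps_P * truth["P"]) * 1e-3  # Beer-Lambert, 1 cm path
absorbance += 0.003 + rng.normal(0, 0.002, grid.size)  # offset + noise

result = unmix_spectrum(Spectrum(grid, absorbance), refs)

print("species   truth (uM)   recovered (uM)")
for sp, got in [("S", result.c_S_uM), ("ES", result.c_ES_uM),
                ("P", result.c_P_uM)]:
    print(f"{sp:7s}  {truth[sp]:10.2f}   {got:13.3f}")
baseline_650 = result.p4 + result.p5 * 650.0 ** 3
print(f"baseline at 650 nm = {baseline_650:.4f} AU (injected 0.003)")
print(f"residual rms = {result.residual_rms:.4f} AU (noise sd 0.002)")
# The recovered concentrations match the generating mixture to within
# the noise floor; the flat offset is shared between the baseline (p4)
# and the nearly flat scatter term (p5*lambda^3) over this window.
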