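"""Measure the ES-complex formation rate constant from a synthetic
no-donor experiment (0.5 uM BchNB, 20 uM Pchlide).

Generates the pre-incubation scenario, unmixes the binding stage, and
fits the ES trace with the plateau one-phase association model after
the 10 s instrument dead time.
"""

from dporkin.kinfit import fit_one_phase
from dporkin.recovery import unmix_stage
from dporkin.synth import generate_experiment, get_scenario

scenario = get_scenario("preincubation")
experiment = generate_experiment(scenario, seed=1)
series = unmix_stage(experiment, stage_index=0)  # no-donor binding stage

fit = fit_one_phase(series.time_s, series.c_ES_uM)
k, dk = fit.params["k"], fit.stderr["k"]
print(f"spectra analyzed : {len(series)} (5 s sampling, 10 s dead time)")
print(f"ES plateau       : {fit.params['plateau']:.3f} uM "
      f"(site capacity 1.0 uM for 0.5 uM BchNB)")
print(f"k_ES             : {k * 1e3:.1f} +- {dk * 1e3:.1f} x10^-3 s^-1 "
      f"(generated at 23.0)")
print(f"R^2              : {fit.r_squared:.4f}")
# The recovered rate constant sits a few percent below the generating
# pseudo-first-order value because 1 uM of bound substrate slightly
# depletes the 20 uM Pchlide pool over the rise.
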