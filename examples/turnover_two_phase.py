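"""Biphasic product formation under turnover conditions.

Generates the substrate-initiated turnover scenario (donor present from
the start), unmixes the full series, and compares one- vs two-phase
association fits of the Chlide trace by AICc.
"""

from dporkin.kinfit import fit_one_phase, fit_two_phase, select_model
from dporkin.recovery import unmix_stage
from dporkin.synth import generate_experiment, get_scenario

experiment = generate_experiment(get_scenario("pchlide_initiated"), seed=1)
series = unmix_stage(experiment, stage_index=0)

one = fit_one_phase(series.time_s, series.c_P_uM)
two = fit_two_phase(series.time_s, series.c_P_uM)
choice = select_model(one, two)

print(f"one-phase AICc : {one.aicc:.1f}")
print(f"two-phase AICc : {two.aicc:.1f}")
print(f"selected       : {choice.chosen.model} ({choice.reason})")
print(f"k_P(fast)      : {two.params['k_fast'] * 1e3:.1f} x10^-3 s^-1 "
      f"(generated at 12.2)")
print(f"k_P(slow)      : {two.params['k_slow'] * 1e3:.2f} x10^-3 s^-1 "
      f"(generated at 1.2)")
# The two catalytic site classes in the generator produce genuinely
# biphasic product formation, and AICc picks the two-phase model.
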