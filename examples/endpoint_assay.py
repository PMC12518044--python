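"""Endpoint activity assay: quench absorbance -> specific activity -> TOF.

Reproduces the worked turnover-frequency example: a specific activity of
3.01 nmol Chlide min^-1 mg_BchNB^-1 at the 206 kDa BchNB molar mass.
"""

from dporkin.assay import (AssayRecord, specific_activity,
                           tof_from_specific_activity)

# one replicate: 100 uL reaction quenched into 500 uL 80% acetone
rec = AssayRecord(a666=0.100, a666_control=0.010, reaction_minutes=8.0,
                  volume_mL=0.1, bchnb_conc_uM=0.05)
res = specific_activity(rec)
print(f"Chlide in quench  : {res.chlide_quench_uM:.3f} uM "
      f"({res.chlide_nmol:.3f} nmol)")
print(f"specific activity : {res.specific_activity:.1f} nmol min^-1 mg^-1")
print(f"TOF               : {res.tof_per_min:.3f} min^-1 "
      f"= {res.tof_per_hour:.1f} h^-1")

# the published worked example
tof = tof_from_specific_activity(3.01, molar_mass=206_000.0)
print(f"3.01 nmol/min/mg at 206 kDa -> TOF = {tof:.1f} per hour")
# The control absorbance is subtracted before the Beer-Lambert
# conversion; TOF is specific activity x molar mass, reported per hour.
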