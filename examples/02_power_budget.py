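"""Powered-flight power budget: available vs minimum mechanical power.

Power available is flight-muscle mass times an allometric burst power
(calibrated: ~107 W/kg at 1 kg, exponent ~ -0.26); minimum power is the bottom
of the U-shaped induced + parasite + profile power curve, reported per body
drag coefficient.  A permutation is feasible when available >= minimum.
"""
from paleoflight import AeroConfig, builtin_fixtures, fit_muscle_power_allometry
from paleoflight.report import power_table, render_report

cfg = AeroConfig()
coeff, exp = fit_muscle_power_allometry()
print(f"calibrated burst power: s(m) = {coeff:.1f} * m^{exp:.3f} W per kg muscle")
print()
df = power_table(builtin_fixtures(), cfg)
print(render_report(df).to_string(index=False))
print()
print("Archaeopteryx and Microraptor clear their requirements at every Cd;")
print("the scansoriopterygids fail under realistic drag (Cd 0.4-0.5) except")
print("at their lightest mass estimates - powered flight is implausible.")
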