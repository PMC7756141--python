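"""Wing loading of the built-in fixtures against the flight thresholds.

Wing loading (body weight / lifting area, N m^-2) is the first feasibility
screen: above 245 N m^-2 no form of flight is considered possible, and extant
gliders span 9-143 N m^-2.  Cells come from estimated wing geometry, so treat
them as reconstruction-dependent, not measured.
"""
from paleoflight import AeroConfig, builtin_fixtures
from paleoflight.report import loading_table, render_report

cfg = AeroConfig()
df = loading_table(builtin_fixtures(), cfg)
print(render_report(df).to_string(index=False))
print()
below = df["flight_possible"].mean()
print(f"{below:.0%} of permutations fall below the 245 N m^-2 ceiling;")
print("the bat-style (BBW) wings sit inside the extant-glider envelope, while")
print("the heavier forewing-only (MFW) permutations drift above it.")
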