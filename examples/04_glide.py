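"""Gliding performance: best glide, sink rate, glide ratio, banked turns.

Best glide maximises horizontal distance per height lost; the banked-turn
radius (24 degrees) is stall-limited and scales with wing loading, so highly
loaded wings must fly fast and turn wide.
"""
from paleoflight import AeroConfig, best_glide, builtin_fixtures, height_loss_per_distance
from paleoflight.wings import build_wing_model

cfg = AeroConfig()
fixtures = builtin_fixtures()
for sid, model, mass in (("STM 31-2", "MFW", 0.38), ("STM 31-2", "BBW", 0.38),
                         ("Berlin", "MFW", 0.20), ("BMNHC PH881", "MFW", 0.18)):
    spec = fixtures.get(sid)
    sol = best_glide(mass, build_wing_model(spec, model, cfg), cfg, cd_body=0.4)
    print(f"{spec.taxon:28s} {model} {mass} kg: glide {sol.V_bestglide_m_s:5.2f} m/s, "
          f"sink {sol.sink_at_bestglide_m_s:4.2f} m/s, ratio {sol.glide_ratio:5.2f}, "
          f"turn radius {sol.turn_radius_m:5.1f} m "
          f"(height loss {height_loss_per_distance(sol.glide_ratio):.3f} per m)")
print()
print("The membrane-winged scansoriopterygids glide faster, sink faster and")
print("turn wider than similar-sized paravians: workable but poor gliders.")
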