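"""Terrestrial take-off: sprinting, leaping, flap-assisted running, WAIR.

A running launch needs the stall-based minimum flight speed; flapping adds
thrust and lift on top of leg drive.  The simulation reports the time to
lift >= weight (or none within the 20 s horizon).
"""
from paleoflight import (AeroConfig, builtin_fixtures, flap_run_simulate,
                         leap_takeoff, sprint_speed, takeoff_speed,
                         wair_capability)
from paleoflight.wings import build_wing_model

cfg = AeroConfig()
yi = builtin_fixtures().get("STM 31-2")
bbw = build_wing_model(yi, "BBW", cfg)

v_sprint = sprint_speed(yi, cfg)
print(f"Yi sprint speed: {v_sprint:.2f} m/s")
for mass in yi.mass_hypotheses_kg:
    v_to = takeoff_speed(mass, bbw, 1.5, cfg)
    print(f"  mass {mass} kg: stall speed {v_to:.2f} m/s "
          f"({v_to / v_sprint:.2f}x sprint)")
print()
for cl in (2.0, 1.5, 1.0):
    res = flap_run_simulate(yi, bbw, cl, "bird", cfg, mass_kg=0.38)
    print(f"flap-run, bat-area wing, bird wingbeat, Cl={cl}: "
          f"take-off at {res.t_takeoff_s} s" if res.achieved else
          f"flap-run, Cl={cl}: no take-off within 20 s")
leap = leap_takeoff(yi, bbw, cfg, with_flapping=True, mass_kg=0.38)
print(f"leap launch {leap.launch_velocity_m_s:.2f} m/s vs stall "
      f"{leap.V_takeoff_m_s:.2f} m/s -> achieves: {leap.achieves_takeoff}")
wair = wair_capability(yi, bbw, 1.5, "bird", cfg, mass_kg=0.38)
print(f"WAIR lift fraction {wair.lift_fraction_of_weight:.2f} of body weight "
      f"-> level {wair.level}")
print()
print("Only the lighter masses under the bat-area wing with a bird wingbeat")
print("achieve a running take-off, and slowly; leaping never suffices; modest")
print("level-I wing-assisted incline running remains possible.")
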