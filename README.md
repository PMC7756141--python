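# paleoflight

Aerodynamic feasibility analysis for the membrane-winged scansoriopterygid
theropods *Yi qi* and *Ambopteryx longibrachium*, with the similar-sized
paravians *Archaeopteryx* and *Microraptor* as comparators. The package is a
reusable, tested implementation of the full reasoning chain used to ask
whether a fossil could fly:

1. **wing reconstruction** — four planform hypotheses (maniraptoran
   forewing-only `MFW`, bat-like fore+hind `BBW`, pterosaur-like `PTW`,
   frog-like webbing `FRW`) built from skeletal anchor points or supplied as
   explicit span/area;
2. **wing loading** — W/S = mg/S (N m⁻²), screened against the 245 N m⁻²
   any-flight ceiling and the 9–143 N m⁻² extant-glider envelope;
3. **powered-flight power budget** — the U-shaped power-required curve
   P(V) = P_ind + P_par + P_pro with
   P_ind = k(mg)²/(2ρV·πb²/4), P_par = ½ρV³S_b C_db,
   P_pro = (C_pro/Ra)·P_am, compared against burst power available
   P_av = f_m·m·s(m) with s(m) ≈ 107·m^(−0.26) W per kg of flight muscle;
4. **terrestrial take-off** — stall speed V_to = √(2mg/ρSC_L) vs allometric
   sprint speed, ballistic leaping, time-stepped flap-assisted running (lift
   and stroke-plane-resolved thrust from the resultant wing speed
   V_r = √(V² + V_f²)), and wing-assisted incline running (WAIR);
5. **gliding** — glide polar under the shallow-glide approximation, best
   glide speed and ratio, minimum sink, and the stall-limited 24°-bank turn
   radius r = 2n(m/S)/(ρC_L,max tanφ), n = 1/cosφ.

It is aimed at comparative biomechanists and palaeontologists who want to
re-run the feasibility analysis under their own mass estimates, wing
reconstructions or aerodynamic assumptions: every constant lives in
`AeroConfig`, and specimens are plain CSV/JSON records.

A `synthetic_data` module generates seeded glider and powered-flier
populations whose wing loadings are exact by construction, so the whole
pipeline is testable end to end without any fossil data.

**A caution on the built-in fixtures.** The measured wing reconstructions for
these specimens were published only in supplementary material that this
package does not bundle. The built-in fixtures therefore carry *estimated*
geometry, inverted from the published glide-performance and turn-radius
tables, and are flagged (`geometry_estimated`, `segments_placeholder`).
Supply measured values via `builtin_fixtures(override_path=...)` or your own
specimen file; reports can mask estimated cells (`--mask-estimated`).

## Worked example

```python
from paleoflight import AeroConfig, builtin_fixtures, best_glide, flap_run_simulate
from paleoflight.wings import build_wing_model, wing_loading

cfg = AeroConfig()
yi = builtin_fixtures().get("STM 31-2")          # Yi qi holotype
bbw = build_wing_model(yi, "BBW", cfg)           # bat-style wing, estimated

print(wing_loading(0.38, bbw, cfg).wing_loading_N_m2)   # 43.5 N m^-2
sol = best_glide(0.38, bbw, cfg, cd_body=0.4)
print(sol.V_bestglide_m_s, sol.glide_ratio)             # 10.07 m/s, 10.33
run = flap_run_simulate(yi, bbw, cl=2.0, wingbeat_model="bird", config=cfg,
                        mass_kg=0.38)
print(run.t_takeoff_s)                                  # 4.88 s
```

A wing loading of 43.5 N m⁻² sits comfortably inside the extant-glider
envelope; a glide ratio of about 10 means 1 m of height buys ~10 m of
horizontal travel (a mediocre glider); and a flap-assisted run only reaches
take-off after ~5 s of sprinting under the most generous lift coefficient —
at C_L = 1.5 it takes over 10 s and at C_L = 1 it never lifts off. The
`examples/` directory walks through each capability
(`python examples/01_wing_loading.py` …), and the `paleoflight` CLI writes
the same tables to CSV (`paleoflight report --out results/`).

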