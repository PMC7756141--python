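# Methods

This note documents the models implemented in `paleoflight`, the defaults and
how they were chosen, what the synthetic data emulate, and the limits of what
the tests demonstrate.

## Specimens and units

A specimen is one individual with a *set* of body-mass hypotheses (fossil
masses are estimates, and the analysis is run as a permutation over them), a
flight-muscle mass fraction (default 0.10, with 0.08 as the conservative
alternative for non-paravian pennaraptorans), named skeletal segment lengths,
and optional per-wing-model span/area. Everything is SI internally; the
CSV/JSON loaders convert from mm/g when a row carries `length_unit`/
`mass_unit` columns. Validation enforces positive lengths, ascending distinct
masses, and aspect ratio > 1 for membrane wing surfaces (the frog-style
webbing is exempt).

### Built-in fixtures and estimated geometry

The published wing reconstructions (span, area, frontal areas, wingbeat
frequencies) for these taxa live in supplementary material not bundled here.
Rather than ship empty fixtures, the package back-estimates geometry from the
published glide-performance tables, which are functions of exactly the
quantities we need:

* **span** from the best-glide condition: at best glide the induced and
  constant-coefficient drag are equal, so the induced drag is
  mg/(2·ratio) and b² = k(mg)²/(½ρπ·D_ind·V_bg²);
* **area** from the stall-limited 24°-bank turn radius,
  S = 2n·m/(ρ C_L,max tanφ · r) with C_L,max = 1.5 and n = 1/cosφ.

Estimates from different mass rows of the same specimen agree to 2–10% and
are averaged; the resulting aspect ratios are anatomically plausible (both
scansoriopterygids ≈ 5.5 under the bat model; *Archaeopteryx* 7.5,
*Microraptor* 8–9). These values are synthetic stand-ins: they are flagged
`estimated`, reports can mask cells derived from them, and measured values
can be injected through an override file. Segment lengths in the fixtures
are likewise plausible placeholders constructed to reproduce the published
anatomical ratios (styliform fraction 42%/32%, forelimb = 4.65× femur,
deltopectoral crest 19%/22%/29%/34% of humerus, crural indices 1.17/1.25,
manual phalangeal indices 1.7 and 4.35).

## Wing planforms

With explicit geometry the builder is a pass-through. Otherwise each model
is a polygon over anatomical anchors (shoulder, elbow, wrist, styliform tip,
digit IV tip; ankle for the bat model, knee for the pterosaur model; digit
tips only for the frog webbing), with the arm fully extended along the
leading edge. One wing's polygon area (shapely) is doubled and a body strip
(body width × mean chord, excluded for the frog model) added; span is twice
the spanwise extent plus body width. The templates guarantee the ordering
FRW ≤ MFW ≤ BBW and MFW ≤ PTW for any one specimen, matching the anatomical
argument that the frog webbing is vastly smaller and the bat/pterosaur
membranes larger than the forewing alone. The polygon templates are
deliberately crude — their role is to propagate *relative* area hypotheses,
not to replace measured reconstructions.

## Wing-loading thresholds

flight_possible ⇔ W/S ≤ 245 N m⁻²; in_glider_envelope ⇔ 9 ≤ W/S ≤ 143 N m⁻².
Both bounds inclusive (the sources use "below" loosely; inclusivity is
stated and tested). 157 N m⁻² — the contested *Kuehneosaurus* extension —
falls outside the envelope by design.

## Power budget

P(V) = P_ind + P_par + P_pro with the standard decomposition given in the
README. Choices worth noting:

* **induced power** uses the actuator-disc area πb²/4 and induced factor
  k = 1.2;
* **body frontal area** uses the classic allometry 0.00813·m^0.666 m²;
* **profile power** is speed-independent, (C_pro/Ra)·P_am with C_pro = 8.4
  and P_am the closed-form minimum of P_ind + P_par (stationarity of
  A/V + BV³ at V* = (A/3B)^¼). With profile power off, V_mp reduces to that
  closed form, which the tests exploit;
* **minimisation** is a 1000-point coarse grid on 0.1–100 m/s (which also
  guards against non-unimodal curves, raising a diagnostic error) followed by
  bounded Brent refinement to ~1e-6 relative on speed. A brute-force
  0.001 m/s grid is the test oracle (agreement ≤ 0.1%).

**Power available** is f_m·m·s(m). The burst specific power s(m) = c·m^e is
*calibrated*: a log-log least-squares fit to the ten distinct published
(mass, power-available) pairs for 0.18–0.95 kg specimens at a 10% muscle
fraction gives c = 107.2 W kg⁻¹ and e = −0.260, reproducing every anchor to
0.11%. The fit function ships in the package and the defaults are its
rounded output; the test suite re-derives the fit and checks the defaults
against it.

**Specific lift** uses the same logic with burst lift per kg muscle; the
default capacity is allometric (84·m^−0.26 N kg⁻¹), placing the pass/fail
boundary at a 10% muscle fraction between 0.45 and 0.7 kg — the published
pattern in which only the heaviest *Yi* estimate fails the lift criterion.

## Terrestrial take-off

* **Stall speed** V_to = √(2mg/(ρSC_L)).
* **Sprint speed** v = a·leg^p·m^q with defaults a = 12.5, p = 0.5, q = 0 — a
  constant-Froude model (Fr ≈ 16) over total hindlimb length, giving
  ~4.7 m/s for *Yi*. The allometry is configurable and a log-log OLS fitter
  (with confidence intervals) is provided for parameter recovery.
* **Leaping**: ballistic launch speed c_leap·√(g·h_hip), c_leap = 2
  (≈ 0.3 m vertical leap for *Yi*); with flapping, one flap's airspeed adds
  vectorially. Launch succeeds if the effective airspeed reaches V_to. For
  both scansoriopterygids this fails at every permutation, with or without
  flapping.
* **Flap-running**: explicit Euler integration (Δt = 0.01 s, 20 s horizon,
  convergence under step halving < 2%). Wingbeat frequency follows the
  standard allometry f = m^(3/8) g^(1/2) b^(−23/24) S^(−1/3) ρ^(−3/8)
  ("bird"), with a ×0.65 "bat" variant (the sources contrast the two without
  printing either). Flapping speed is taken at the ⅔-semispan station,
  V_f = 2Φf·(⅔·b/2). Per step: lift ½ρSC_L V_r², thrust
  ½ρSC_L V_f²·cos(θ_sp), leg drive a_leg·(1 − V/V_sprint) while below sprint
  speed, and opposing body drag plus the flapping wing's own induced and
  profile drag. Including wing drag is a deliberate extension of the minimal
  force list: without the induced-drag cost of flapping at high C_L, any
  thrust surplus accelerates the runner indefinitely and the empirical
  "no take-off at C_L = 1" outcome would be unreachable.
* **WAIR** evaluates the same wing lift at a slow reference run speed
  (1.5 m/s, the juvenile-galliform range) and grades lift/weight against
  level thresholds (level I ≥ 0.2, level II ≥ 0.5; provisional, configurable).

### Calibration of the free launch constants

Flap amplitude (1.2 rad), stroke-plane angle (62°), leg acceleration
(1.0 m s⁻²) and the WAIR level-I threshold (0.2) are not printed in the
sources. They were set once, against the estimated fixture geometry, so that
the published qualitative pattern is reproduced and then frozen: *Yi* under
the bat-area wing with a bird wingbeat lifts off at ≈4.9 s (0.38 kg) and
≈6.9 s (0.45 kg) bracketing the published "5–6 s", takes > 7 s at C_L = 1.5,
never at C_L = 1, and never at 0.7 kg or under a bat wingbeat; *Ambopteryx*
never achieves a flap-running take-off; bird-frequency WAIR reaches level I
for *Yi* across all masses while *Ambopteryx* reaches it only under the
bat-area wing with bird flapping. These constants are conventions of the
model, not measurements, and all of them are `AeroConfig` fields.

## Gliding

Shallow-glide approximation (L ≈ W): sink V_s = V·D(V)/(mg) with
D = induced + body + wing-profile drag; best glide maximises V/V_s
(= mg/D), minimum sink is V_bg/3^¼ analytically. The wing profile drag
coefficient is fixed at 0.014 (standard for membrane sections); a
"profile-constant over aspect ratio" form was rejected because it produces
drag coefficients an order of magnitude too large. With this model, moving
the body drag coefficient from 0.4 to 0.5 reproduces the published changes
in glide speed and ratio to ~1% for the specimens used to estimate geometry.
The banked-turn radius is stall-limited (formula in the README), hence
independent of the drag coefficients — the published tables print identical
radii across drag blocks for the *Yi* rows, which motivated this choice; a
few comparator rows differ slightly across blocks, so the source program's
radius convention is evidently not purely stall-limited, and the load-factor
term can be toggled off. The shallow-glide approximation overstates
performance at ratios near 1; all fixtures sit at ratios ≥ 7 where the error
is below ~1%.

## Synthetic populations

Gliders: mass log-uniform on 0.01–3 kg (extant gliders top out near 2.5–3 kg),
wing loading uniform on 9–143 N m⁻², aspect ratio uniform on 4–8, muscle
fraction 0.08–0.12. Powered fliers shift loading to 30–180 N m⁻² and aspect
ratio to 7–12. Geometry is derived (S = mg/WL, b = √(Ra·S)), so the drawn
loading is recovered exactly; segments are back-filled from proportional
templates with optional log-normal noise (CV 0.05) — they only need to be
plausible enough for the sprint/leap/ratio stages to run. One seeded
generator per call; identical seeds give identical tables bit for bit.

What passing tests show — and don't. The synthetic populations validate the
*machinery* (identities, determinism, monotonicity, classification); they do
not attempt to match real extant-glider species values, wing allometry or
phylogenetic structure, so population-level conclusions about real gliders
cannot be read off them.

## Numerical conventions

Optimisation brackets are 0.1–100 m/s; curves are checked for unimodality on
a 1000-point grid before refinement and a diagnostic error is raised
otherwise. Euler integration declares take-off at the first step with
lift ≥ weight; the take-off time is therefore quantised to Δt. Quartiles use
linear interpolation. Report tables round to 2 decimals (the precision of
the published tables); machine CSVs keep full precision.

## Known limitations

* No wing cross-section, camber, membrane tension or aeroelasticity: the
  lift and drag coefficients assume a competent membrane aerofoil, which is
  generous for these taxa.
* No metabolic power, intermittent flight, wind, or non-equilibrium gliding.
* Fixture geometry is estimated from published performance tables, not
  measured; absolute fixture numbers inherit that uncertainty (relative and
  threshold statements are much more robust to it).
* The wrist-fold/radiale-angle observations are carried as specimen notes
  only; no kinematic model of wing folding is attempted.
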