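"""Terrestrial launch analysis: take-off speed, sprinting, leaping,
flap-assisted running and wing-assisted incline running (WAIR).

The flap-running model integrates a run with flapping wings forward in time:
leg drive accelerates the body toward its sprint speed while the flapping wing
adds lift and stroke-plane-resolved thrust from the resultant wing speed
``V_r = sqrt(V^2 + V_f^2)``, where ``V_f`` is the mean flapping speed at the
2/3-semispan station.  Body drag and the flapping wing's own induced and
profile drag oppose the motion - without that induced-drag cost a wing flapped
at high lift coefficient would supply free thrust indefinitely.  Take-off is
declared when lift first reaches body weight.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .config import AeroConfig
from .specimens import SchemaError, Specimen
from .wings import WingPlanform


@dataclass(frozen=True)
class FlapRunResult:
    t_s: np.ndarray
    V_m_s: np.ndarray
    lift_fraction: np.ndarray
    t_takeoff_s: float | None   # None when lift never reached weight

    @property
    def achieved(self) -> bool:
        return self.t_takeoff_s is not None


@dataclass(frozen=True)
class LeapResult:
    launch_velocity_m_s: float
    effective_airspeed_m_s: float
    V_takeoff_m_s: float
    achieves_takeoff: bool


@dataclass(frozen=True)
class WairResult:
    lift_fraction_of_weight: float
    level: str   # "none", "I" or "II"


@dataclass(frozen=True)
class TakeoffResult:
    V_takeoff_m_s: float
    V_sprint_m_s: float
    ratio_takeoff_sprint: float
    leap: LeapResult
    flaprun: FlapRunResult


def takeoff_speed(mass_kg: float, planform: WingPlanform, cl: float,
                  config: AeroConfig | None = None) -> float:
    """Stall-based minimum flight speed ``V_to = sqrt(2 m g / (rho S Cl))``."""
    if cl <= 0:
        raise ValueError("lift coefficient must be > 0")
    cfg = config or AeroConfig()
    return math.sqrt(2.0 * mass_kg * cfg.g
                     / (cfg.rho_air * planform.area_S_m2 * cl))


def sprint_speed(spec: Specimen, config: AeroConfig | None = None) -> float:
    """Maximum sprint speed from the allometry ``v = a * leg^p * m^q``.

    ``leg`` is the total hindlimb length (m); the default exponents make this
    a constant-Froude-number model (speed scaling with the square root of leg
    length), with the largest mass hypothesis setting any mass dependence.
    """
    cfg = config or AeroConfig()
    if "hindlimb_total" not in spec.segments_m:
        raise SchemaError(f"{spec.specimen_id}: sprint speed needs hindlimb_total")
    leg = spec.segments_m["hindlimb_total"]
    mass = spec.mass_hypotheses_kg[-1]
    return cfg.sprint_coeff_a * leg ** cfg.sprint_exp_p * mass ** cfg.sprint_exp_q


def fit_sprint_allometry(leg_m, mass_kg, speeds_m_s):
    """Recover (a, p, q) of the sprint allometry by log-log least squares.

    Returns the statsmodels OLS results for
    ``log v = log a + p log leg + q log m`` (confidence intervals via
    ``res.conf_int()``; parameter order: intercept ``log a``, then p, then q).
    """
    X = sm.add_constant(np.column_stack([np.log(leg_m), np.log(mass_kg)]))
    return sm.OLS(np.log(speeds_m_s), X).fit()


def wingbeat_frequency(mass_kg: float, planform: WingPlanform,
                       config: AeroConfig | None = None,
                       model: str | None = None) -> float:
    """Allometric wingbeat frequency (Hz).

    The "bird" model uses the standard scaling
    ``f = m^(3/8) g^(1/2) b^(-23/24) S^(-1/3) rho^(-3/8)``; the "bat" model
    applies a constant reduction factor, reflecting the slower wingbeats of
    membrane-winged mammals of comparable size.
    """
    cfg = config or AeroConfig()
    which = model or cfg.wingbeat_model
    f = (mass_kg ** (3.0 / 8.0) * cfg.g ** 0.5
         * planform.span_b_m ** (-23.0 / 24.0)
         * planform.area_S_m2 ** (-1.0 / 3.0)
         * cfg.rho_air ** (-3.0 / 8.0))
    if which == "bat":
        f *= cfg.bat_frequency_factor
    elif which != "bird":
        raise ValueError(f"unknown wingbeat model {which!r}")
    return f


def flapping_speed(frequency_hz: float, planform: WingPlanform,
                   config: AeroConfig | None = None) -> float:
    """Mean flapping speed at the 2/3-semispan station, ``2 Phi f (2/3)(b/2)``."""
    cfg = config or AeroConfig()
    return 2.0 * cfg.flap_amplitude_rad * frequency_hz \
        * (2.0 / 3.0) * (planform.span_b_m / 2.0)


def _wing_forces(V: float, v_f: float, mass_kg: float, planform: WingPlanform,
                 cfg: AeroConfig, cl: float) -> tuple[float, float, float]:
    """(lift, thrust, wing drag) of the flapping wing at forward speed V."""
    vr2 = V * V + v_f * v_f
    q_wing = 0.5 * cfg.rho_air * vr2
    lift = q_wing * planform.area_S_m2 * cl
    thrust = 0.5 * cfg.rho_air * planform.area_S_m2 * cl * v_f * v_f \
        * math.cos(math.radians(cfg.stroke_plane_deg))
    induced = 0.0
    if vr2 > 0:
        induced = cfg.k_induced * lift ** 2 \
            / (0.5 * cfg.rho_air * vr2 * math.pi * planform.span_b_m ** 2)
    profile = q_wing * planform.area_S_m2 * cfg.cd_profile_glide
    return lift, thrust, induced + profile


def flap_run_simulate(spec: Specimen, planform: WingPlanform, cl: float,
                      wingbeat_model: str | None = None,
                      config: AeroConfig | None = None,
                      mass_kg: float | None = None,
                      dt: float | None = None) -> FlapRunResult:
    """Forward-time simulation of a flap-assisted running take-off.

    Explicit Euler integration (default step 0.01 s, horizon 20 s).  The run
    ends at the first step where wing lift reaches body weight; otherwise
    ``t_takeoff_s`` is ``None``.
    """
    cfg = config or AeroConfig()
    step = cfg.dt if dt is None else dt
    mass = spec.mass_hypotheses_kg[0] if mass_kg is None else mass_kg
    weight = mass * cfg.g
    f = wingbeat_frequency(mass, planform, cfg, wingbeat_model)
    v_f = flapping_speed(f, planform, cfg)
    v_sprint = sprint_speed(spec, cfg)
    s_body = cfg.frontal_area(mass)

    n_steps = int(round(cfg.horizon_s / step))
    t_hist = np.empty(n_steps + 1)
    v_hist = np.empty(n_steps + 1)
    l_hist = np.empty(n_steps + 1)
    V = 0.0
    t_takeoff = None
    last = n_steps
    for i in range(n_steps + 1):
        lift, thrust, wing_drag = _wing_forces(V, v_f, mass, planform, cfg, cl)
        t_hist[i], v_hist[i], l_hist[i] = i * step, V, lift / weight
        if lift >= weight:
            t_takeoff = i * step
            last = i
            break
        leg = cfg.leg_accel_max * max(0.0, 1.0 - V / v_sprint)
        body_drag = 0.5 * cfg.rho_air * V * V * s_body * cfg.cd_body_takeoff
        accel = leg + (thrust - body_drag - wing_drag) / mass
        V = max(0.0, V + accel * step)
        if not math.isfinite(V):
            raise FloatingPointError("flap-run integration produced non-finite state")
    return FlapRunResult(t_s=t_hist[:last + 1], V_m_s=v_hist[:last + 1],
                         lift_fraction=l_hist[:last + 1], t_takeoff_s=t_takeoff)


def leap_takeoff(spec: Specimen, planform: WingPlanform,
                 config: AeroConfig | None = None, with_flapping: bool = False,
                 cl: float | None = None, mass_kg: float | None = None) -> LeapResult:
    """Ballistic leap launch check.

    Launch speed is ``c_leap * sqrt(g * hip height)`` (hip height taken as the
    total hindlimb length).  With flapping enabled, one flap's airspeed is
    added vectorially.  Take-off requires the effective airspeed to reach the
    stall-based minimum flight speed.
    """
    cfg = config or AeroConfig()
    if "hindlimb_total" not in spec.segments_m:
        raise SchemaError(f"{spec.specimen_id}: leap model needs hindlimb_total")
    mass = spec.mass_hypotheses_kg[0] if mass_kg is None else mass_kg
    cl_use = max(cfg.cl_set) if cl is None else cl
    hip = spec.segments_m["hindlimb_total"]
    launch = cfg.leap_coeff * math.sqrt(cfg.g * hip)
    effective = launch
    if with_flapping:
        f = wingbeat_frequency(mass, planform, cfg)
        effective = math.hypot(launch, flapping_speed(f, planform, cfg))
    v_to = takeoff_speed(mass, planform, cl_use, cfg)
    return LeapResult(launch_velocity_m_s=launch, effective_airspeed_m_s=effective,
                      V_takeoff_m_s=v_to, achieves_takeoff=effective >= v_to)


def wair_capability(spec: Specimen, planform: WingPlanform, cl: float,
                    wingbeat_model: str | None = None,
                    config: AeroConfig | None = None,
                    mass_kg: float | None = None) -> WairResult:
    """Wing-assisted incline running capability.

    Evaluates the flapping wing's lift at a slow reference run speed (default
    1.5 m/s, in the range observed for incline-running juvenile galliforms)
    and grades the lift-to-weight fraction against the configured level
    thresholds.
    """
    cfg = config or AeroConfig()
    mass = spec.mass_hypotheses_kg[0] if mass_kg is None else mass_kg
    f = wingbeat_frequency(mass, planform, cfg, wingbeat_model)
    v_f = flapping_speed(f, planform, cfg)
    lift, _thrust, _drag = _wing_forces(cfg.wair_speed, v_f, mass, planform, cfg, cl)
    fraction = lift / (mass * cfg.g)
    if fraction >= cfg.wair_level2_fraction:
        level = "II"
    elif fraction >= cfg.wair_level1_fraction:
        level = "I"
    else:
        level = "none"
    return WairResult(lift_fraction_of_weight=fraction, level=level)


def takeoff_analysis(spec: Specimen, planform: WingPlanform, cl: float,
                     wingbeat_model: str | None = None,
                     config: AeroConfig | None = None,
                     mass_kg: float | None = None) -> TakeoffResult:
    """Bundle stall speed, sprint comparison, leap and flap-run for one permutation."""
    cfg = config or AeroConfig()
    mass = spec.mass_hypotheses_kg[0] if mass_kg is None else mass_kg
    v_to = takeoff_speed(mass, planform, cl, cfg)
    v_sprint = sprint_speed(spec, cfg)
    return TakeoffResult(
        V_takeoff_m_s=v_to, V_sprint_m_s=v_sprint,
        ratio_takeoff_sprint=v_to / v_sprint,
        leap=leap_takeoff(spec, planform, cfg, with_flapping=True,
                          cl=cl, mass_kg=mass),
        flaprun=flap_run_simulate(spec, planform, cl, wingbeat_model, cfg,
                                  mass_kg=mass),
    )
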