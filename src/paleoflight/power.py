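"""Mechanical power curve, power available, and the powered-flight verdict.

The power required to fly at airspeed ``V`` is decomposed in the standard way:

* induced power  ``P_ind = k (m g)^2 / (2 rho V Sd)`` with disc area
  ``Sd = pi b^2 / 4`` - the cost of generating lift;
* parasite power ``P_par = 0.5 rho V^3 S_body Cd_body`` - body drag, with
  frontal area from the allometry in :class:`~paleoflight.config.AeroConfig`;
* profile power  ``P_pro = (Cpro / Ra) * P_am`` - wing-section drag, taken as
  speed-independent and proportional to the absolute minimum ``P_am`` of
  ``P_ind + P_par``.

Power available is flight-muscle mass times a mass-specific burst power
``s(m) = coeff * m^exp``; the default coefficients are calibrated by
:func:`fit_muscle_power_allometry` against published power-availability
estimates for 0.18-0.95 kg fossil fliers.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .config import AeroConfig
from .published import power_available_anchors
from .specimens import Specimen
from .wings import WingPlanform, build_wing_model

V_BRACKET = (0.1, 100.0)   # m/s search interval for minimum-power speed


class NonUnimodalError(RuntimeError):
    """The power/drag curve showed multiple grid minima (diagnostic guard)."""


@dataclass(frozen=True)
class PowerVerdict:
    """Power budget for one (mass, wing model) permutation."""

    mass_kg: float
    model: str
    P_available_W: float
    min_power_per_cd: dict   # Cd -> (Vmp m/s, Pmin W)
    feasible_per_cd: dict    # Cd -> P_available >= Pmin

    @property
    def feasible_any(self) -> bool:
        return any(self.feasible_per_cd.values())

    @property
    def feasible_all(self) -> bool:
        return all(self.feasible_per_cd.values())


def _power_terms(mass_kg: float, planform: WingPlanform, config: AeroConfig,
                 cd_body: float) -> tuple[float, float]:
    """Coefficients (A, B) of P_ind + P_par = A/V + B V^3."""
    mg = mass_kg * config.g
    disc = math.pi * planform.span_b_m ** 2 / 4.0
    A = config.k_induced * mg ** 2 / (2.0 * config.rho_air * disc)
    B = 0.5 * config.rho_air * config.frontal_area(mass_kg) * cd_body
    return A, B


def absolute_minimum_power(mass_kg: float, planform: WingPlanform,
                           config: AeroConfig, cd_body: float) -> float:
    """Closed-form minimum of ``P_ind + P_par`` over airspeed.

    Stationarity of ``A/V + B V^3`` gives ``V* = (A / 3B)^{1/4}``.
    Degenerate coefficients (A or B zero) make the infimum zero.
    """
    A, B = _power_terms(mass_kg, planform, config, cd_body)
    if A <= 0 or B <= 0:
        return 0.0
    v_star = (A / (3.0 * B)) ** 0.25
    return A / v_star + B * v_star ** 3


def power_required(V, mass_kg: float, planform: WingPlanform,
                   config: AeroConfig | None = None,
                   cd_body: float | None = None):
    """Mechanical power (W) required to fly at airspeed ``V`` (m/s).

    Accepts a scalar or array ``V``; every element must be positive.
    """
    cfg = config or AeroConfig()
    cd = cfg.cd_body_set[0] if cd_body is None else cd_body
    v = np.asarray(V, dtype=float)
    if np.any(v <= 0):
        raise ValueError("airspeed must be > 0")
    A, B = _power_terms(mass_kg, planform, cfg, cd)
    p_pro = 0.0
    if cfg.cpro > 0:
        p_pro = (cfg.cpro / planform.aspect_ratio_Ra) \
            * absolute_minimum_power(mass_kg, planform, cfg, cd)
    out = A / v + B * v ** 3 + p_pro
    return float(out) if np.isscalar(V) else out


def _guard_unimodal(values: np.ndarray, what: str) -> int:
    """Index of the single interior minimum of a sampled curve, or raise."""
    interior = (values[1:-1] < values[:-2]) & (values[1:-1] <= values[2:])
    n_minima = int(np.count_nonzero(interior))
    if n_minima > 1:
        raise NonUnimodalError(f"{what}: {n_minima} local minima on coarse grid")
    if n_minima == 0:   # monotone curve; minimum sits at a bracket edge
        return int(np.argmin(values))
    return int(np.flatnonzero(interior)[0]) + 1


def min_power(mass_kg: float, planform: WingPlanform,
              config: AeroConfig | None = None,
              cd_body: float | None = None) -> tuple[float, float]:
    """Minimum-power speed and minimum power, ``(Vmp m/s, Pmin W)``.

    A 1000-point coarse grid over 0.1-100 m/s first verifies the curve is
    unimodal (raising :class:`NonUnimodalError` otherwise); Brent refinement
    then achieves ~1e-6 relative tolerance on the speed.
    """
    cfg = config or AeroConfig()
    cd = cfg.cd_body_set[0] if cd_body is None else cd_body
    grid = np.linspace(*V_BRACKET, 1000)
    values = power_required(grid, mass_kg, planform, cfg, cd)
    idx = _guard_unimodal(values, "power curve")
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda v: power_required(float(v), mass_kg, planform, cfg, cd),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * max(grid[idx], 1.0)})
    return float(res.x), float(res.fun)


def power_available(mass_kg: float, muscle_fraction: float,
                    config: AeroConfig | None = None) -> float:
    """Burst mechanical power (W) from the flight muscles.

    ``P_avail = fraction * m * s(m)`` with the mass-specific burst power
    allometry from the configuration.
    """
    if not 0 <= muscle_fraction <= 1:
        raise ValueError("muscle_fraction must lie in [0, 1]")
    cfg = config or AeroConfig()
    return muscle_fraction * mass_kg * cfg.muscle_specific_power(mass_kg)


def specific_lift_check(mass_kg: float, muscle_fraction: float,
                        lift_capacity_N_per_kg_muscle: float,
                        config: AeroConfig | None = None) -> tuple[bool, float]:
    """Burst-lift take-off criterion.

    Capable iff the muscles' burst lift covers body weight:
    ``fraction * m * capacity >= m g``.  Returns ``(capable, margin_N)``.
    """
    if lift_capacity_N_per_kg_muscle <= 0:
        raise ValueError("lift capacity must be > 0")
    cfg = config or AeroConfig()
    margin = muscle_fraction * mass_kg * lift_capacity_N_per_kg_muscle \
        - mass_kg * cfg.g
    return margin >= 0, margin


def fit_muscle_power_allometry(anchors=None, muscle_fraction: float = 0.10
                               ) -> tuple[float, float]:
    """Least-squares calibration of the burst-power allometry.

    Fits ``log s = log coeff + exp * log m`` where ``s = P_avail / (fraction m)``
    over the published (mass, power-available) anchor pairs.  Returns
    ``(coeff W/kg, exp)``; the :class:`~paleoflight.config.AeroConfig` defaults
    are this fit rounded to 4 significant figures.
    """
    pairs = anchors if anchors is not None else power_available_anchors()
    m = np.array([p[0] for p in pairs], dtype=float)
    p_avail = np.array([p[1] for p in pairs], dtype=float)
    specific = p_avail / (muscle_fraction * m)
    exp, logc = np.polyfit(np.log(m), np.log(specific), 1)
    return float(np.exp(logc)), float(exp)


def powered_flight_verdict(spec: Specimen, model: str,
                           config: AeroConfig | None = None
                           ) -> list[PowerVerdict]:
    """Power budget per mass hypothesis: available vs minimum required per Cd."""
    cfg = config or AeroConfig()
    planform = build_wing_model(spec, model, cfg)
    verdicts = []
    for mass in spec.mass_hypotheses_kg:
        p_avail = power_available(mass, spec.flight_muscle_fraction, cfg)
        per_cd = {cd: min_power(mass, planform, cfg, cd) for cd in cfg.cd_body_set}
        feasible = {cd: p_avail >= pmin for cd, (_vmp, pmin) in per_cd.items()}
        verdicts.append(PowerVerdict(mass_kg=mass, model=model,
                                     P_available_W=p_avail,
                                     min_power_per_cd=per_cd,
                                     feasible_per_cd=feasible))
    return verdicts
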