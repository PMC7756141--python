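"""Equilibrium gliding: glide polar, best glide, minimum sink, banked turns.

Under the shallow-glide approximation (lift ~ weight, valid for glide ratios
well above 1) the sink rate at airspeed ``V`` is ``V_s = V D(V) / (m g)`` with
total drag

``D(V) = k (m g)^2 / (0.5 rho V^2 pi b^2)  +  0.5 rho V^2 (S_body Cd_body + S Cd_pro)``

(induced + body + wing profile).  Best glide maximises ``V / V_s`` (equivalently
lift over drag); minimum sink minimises ``V_s``.  The banked-turn radius is
stall-limited, ``r = 2 n (m/S) / (rho Cl_max tan(bank))`` with load factor
``n = 1/cos(bank)`` - a formulation independent of the drag coefficients, which
is why it scales purely with wing loading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .config import AeroConfig
from .power import NonUnimodalError, V_BRACKET, _guard_unimodal
from .wings import WingPlanform


@dataclass(frozen=True)
class GlideSolution:
    V_bestglide_m_s: float
    sink_at_bestglide_m_s: float
    glide_ratio: float
    V_minsink_m_s: float
    turn_radius_m: float
    bank_angle_deg: float
    cd_body: float


def _drag_terms(mass_kg: float, planform: WingPlanform, config: AeroConfig,
                cd_body: float) -> tuple[float, float]:
    """Coefficients (A, B) of D(V) = A/V^2 + B V^2."""
    mg = mass_kg * config.g
    A = config.k_induced * mg ** 2 \
        / (0.5 * config.rho_air * math.pi * planform.span_b_m ** 2)
    B = 0.5 * config.rho_air * (config.frontal_area(mass_kg) * cd_body
                                + planform.area_S_m2 * config.cd_profile_glide)
    return A, B


def glide_drag(V, mass_kg: float, planform: WingPlanform,
               config: AeroConfig | None = None, cd_body: float | None = None):
    """Total aerodynamic drag (N) in equilibrium glide at airspeed ``V``."""
    cfg = config or AeroConfig()
    cd = cfg.cd_body_set[0] if cd_body is None else cd_body
    v = np.asarray(V, dtype=float)
    if np.any(v <= 0):
        raise ValueError("airspeed must be > 0")
    A, B = _drag_terms(mass_kg, planform, cfg, cd)
    out = A / v ** 2 + B * v ** 2
    return float(out) if np.isscalar(V) else out


def glide_sink(V, mass_kg: float, planform: WingPlanform,
               config: AeroConfig | None = None, cd_body: float | None = None):
    """Sink rate (m/s) at airspeed ``V`` under the shallow-glide approximation."""
    cfg = config or AeroConfig()
    drag = glide_drag(V, mass_kg, planform, cfg, cd_body)
    return np.asarray(V, dtype=float) * drag / (mass_kg * cfg.g) \
        if not np.isscalar(V) else float(V) * drag / (mass_kg * cfg.g)


def best_glide(mass_kg: float, planform: WingPlanform,
               config: AeroConfig | None = None,
               cd_body: float | None = None) -> GlideSolution:
    """Best-glide point, minimum-sink speed and banked-turn radius.

    The glide ratio (horizontal distance per unit height lost) equals
    ``m g / D(V)`` under the shallow approximation, so best glide minimises
    drag.  A coarse grid guards unimodality before Brent refinement, as for
    the power curve.
    """
    cfg = config or AeroConfig()
    cd = cfg.cd_body_set[0] if cd_body is None else cd_body
    mg = mass_kg * cfg.g
    grid = np.linspace(*V_BRACKET, 1000)
    drag = glide_drag(grid, mass_kg, planform, cfg, cd)
    idx = _guard_unimodal(drag, "glide polar")
    res = minimize_scalar(
        lambda v: glide_drag(float(v), mass_kg, planform, cfg, cd),
        bounds=(grid[max(idx - 1, 0)], grid[min(idx + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-6 * max(grid[idx], 1.0)})
    v_bg = float(res.x)
    ratio = mg / float(res.fun)
    # sink V_s = (A/V + B V^3)/mg has its minimum at V_bg / 3^(1/4)
    A, B = _drag_terms(mass_kg, planform, cfg, cd)
    v_ms = (A / (3.0 * B)) ** 0.25 if (A > 0 and B > 0) else v_bg
    return GlideSolution(
        V_bestglide_m_s=v_bg,
        sink_at_bestglide_m_s=glide_sink(v_bg, mass_kg, planform, cfg, cd),
        glide_ratio=ratio,
        V_minsink_m_s=float(v_ms),
        turn_radius_m=turn_radius(mass_kg, planform, cfg),
        bank_angle_deg=cfg.bank_angle_deg,
        cd_body=cd,
    )


def turn_radius(mass_kg: float, planform: WingPlanform,
                config: AeroConfig | None = None,
                cl_max: float | None = None,
                bank_deg: float | None = None) -> float:
    """Stall-limited radius (m) of a banked gliding turn.

    ``r = 2 n (m/S) / (rho Cl_max tan(bank))`` with load factor
    ``n = 1/cos(bank)`` (or 1 when ``use_load_factor`` is off).  Radius grows
    with wing loading and is independent of the body drag coefficient.
    """
    cfg = config or AeroConfig()
    cl = cfg.cl_max_turn if cl_max is None else cl_max
    bank = cfg.bank_angle_deg if bank_deg is None else bank_deg
    if not 0 < bank < 90:
        raise ValueError("bank angle must lie in (0, 90) degrees")
    phi = math.radians(bank)
    n_load = 1.0 / math.cos(phi) if cfg.use_load_factor else 1.0
    return 2.0 * n_load * (mass_kg / planform.area_S_m2) \
        / (cfg.rho_air * cl * math.tan(phi))


def height_loss_per_distance(glide_ratio: float) -> float:
    """Height lost per unit horizontal distance travelled (1 / glide ratio)."""
    if glide_ratio <= 0:
        raise ValueError("glide ratio must be > 0")
    return 1.0 / glide_ratio
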