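"""Published comparative flight-performance values used as calibration inputs.

These are the printed power and gliding comparison tables for the
scansoriopterygids *Yi qi* and *Ambopteryx longibrachium* and the paravians
*Archaeopteryx* (Berlin specimen) and *Microraptor gui* (BMNHC PH881,
IVPP V13352).  The package uses them in two ways:

* the (mass, power-available) pairs anchor the muscle burst-power allometry
  (see :func:`paleoflight.power.fit_muscle_power_allometry`);
* the glide block is inverted into *estimated* wing spans and areas for the
  built-in fixtures (see :func:`estimate_geometry`), because the raw
  morphometric wing reconstructions were published only in supplementary
  material that is not machine-readable here.

Wing-model codes: MFW = maniraptoran forewing only, BBW = bat-like fore+hind
wing.  Units: kg, W, m s^-1, m.
"""
from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

# taxon, specimen_id, model, mass_kg, Pwr_W, Pmin at Cd 0.1 / 0.4 / 0.5 (W)
POWER_TABLE: list[tuple] = [
    ("Yi qi", "STM 31-2", "MFW", 0.38, 5.24, 3.41, 4.82, 5.09),
    ("Yi qi", "STM 31-2", "BBW", 0.38, 5.24, 3.93, 5.56, 5.88),
    ("Yi qi", "STM 31-2", "MFW", 0.45, 5.94, 4.52, 6.40, 6.77),
    ("Yi qi", "STM 31-2", "BBW", 0.45, 5.94, 6.93, 9.81, 10.40),
    ("Yi qi", "STM 31-2", "MFW", 0.70, 8.23, 9.43, 13.40, 14.10),
    ("Yi qi", "STM 31-2", "BBW", 0.70, 8.23, 14.50, 20.50, 21.70),
    ("Archaeopteryx", "Berlin", "MFW", 0.20, 3.26, 1.59, 2.24, 2.37),
    ("Microraptor gui", "BMNHC PH881", "MFW", 0.18, 3.01, 1.35, 1.91, 2.02),
    ("Microraptor gui", "BMNHC PH881", "MFW", 0.24, 3.73, 2.19, 3.09, 3.27),
    ("Microraptor gui", "IVPP V13352", "MFW", 0.95, 10.32, 8.45, 12.00, 12.60),
    ("Microraptor gui", "IVPP V13352", "MFW", 0.50, 6.42, 3.61, 5.10, 5.39),
    ("Ambopteryx", "STM 0-144", "MFW", 0.23, 3.61, 2.88, 4.07, 4.30),
    ("Ambopteryx", "STM 0-144", "BBW", 0.23, 3.61, 4.35, 6.16, 6.51),
    ("Ambopteryx", "STM 0-144", "MFW", 0.31, 4.51, 4.73, 6.69, 7.08),
    ("Ambopteryx", "STM 0-144", "BBW", 0.31, 4.51, 7.16, 10.10, 10.70),
    ("Ambopteryx", "STM 0-144", "MFW", 0.38, 5.24, 6.65, 9.40, 9.94),
    ("Ambopteryx", "STM 0-144", "BBW", 0.38, 5.24, 10.10, 14.20, 15.00),
]

# taxon, specimen_id, model, mass_kg, then (glide speed, sink, glide ratio,
# bank radius) for body Cd 0.4 and for Cd 0.5
GLIDE_TABLE: list[tuple] = [
    ("Yi qi", "STM 31-2", "MFW", 0.38,
     (10.70, 0.81, 13.30, 21.70), (10.30, 0.85, 12.10, 21.70)),
    ("Yi qi", "STM 31-2", "BBW", 0.38,
     (9.80, 1.02, 9.58, 11.90), (9.40, 1.04, 9.03, 11.90)),
    ("Yi qi", "STM 31-2", "MFW", 0.45,
     (11.30, 0.89, 12.70, 26.10), (11.20, 0.98, 11.50, 26.10)),
    ("Yi qi", "STM 31-2", "BBW", 0.45,
     (10.40, 1.12, 9.30, 14.10), (10.00, 1.11, 8.74, 14.10)),
    ("Yi qi", "STM 31-2", "MFW", 0.70,
     (13.90, 1.26, 11.10, 42.40), (13.30, 1.34, 9.90, 42.40)),
    ("Yi qi", "STM 31-2", "BBW", 0.70,
     (12.30, 1.44, 8.56, 21.70), (11.70, 1.46, 8.00, 21.70)),
    ("Archaeopteryx", "Berlin", "MFW", 0.20,
     (8.00, 0.69, 11.60, 9.01), (7.70, 0.70, 11.00, 8.72)),
    ("Microraptor gui", "BMNHC PH881", "MFW", 0.18,
     (8.00, 0.67, 12.00, 9.95), (7.60, 0.68, 11.20, 9.33)),
    ("Microraptor gui", "BMNHC PH881", "MFW", 0.24,
     (8.90, 0.79, 11.30, 12.60), (8.50, 0.80, 10.60, 11.60)),
    ("Microraptor gui", "IVPP V13352", "MFW", 0.95,
     (10.80, 0.84, 12.80, 19.00), (10.30, 0.86, 11.90, 19.00)),
    ("Microraptor gui", "IVPP V13352", "MFW", 0.50,
     (8.90, 0.68, 13.10, 12.30), (8.50, 0.69, 12.30, 11.60)),
    ("Ambopteryx", "STM 0-144", "MFW", 0.23,
     (11.70, 1.22, 9.59, 33.10), (11.60, 1.34, 8.66, 33.10)),
    ("Ambopteryx", "STM 0-144", "BBW", 0.23,
     (10.70, 1.30, 8.24, 17.70), (10.20, 1.33, 7.67, 16.90)),
    ("Ambopteryx", "STM 0-144", "MFW", 0.31,
     (13.60, 1.55, 8.75, 45.70), (13.60, 1.74, 7.80, 45.70)),
    ("Ambopteryx", "STM 0-144", "BBW", 0.31,
     (11.90, 1.54, 7.73, 21.10), (11.30, 1.58, 7.17, 20.80)),
    ("Ambopteryx", "STM 0-144", "MFW", 0.38,
     (15.10, 1.85, 8.17, 56.40), (15.10, 2.09, 7.22, 56.40)),
    ("Ambopteryx", "STM 0-144", "BBW", 0.38,
     (12.80, 1.73, 7.39, 26.60), (12.20, 1.78, 6.84, 24.10)),
]


def power_available_anchors() -> list[tuple[float, float]]:
    """Distinct (mass kg, power available W) pairs, at 10% flight muscle."""
    return sorted({(row[3], row[4]) for row in POWER_TABLE})


def estimate_geometry(rho: float = 1.225, g: float = 9.81, k_induced: float = 1.2,
                      cl_max_turn: float = 1.5, bank_angle_deg: float = 24.0,
                      use_load_factor: bool = True) -> dict[tuple[str, str], dict]:
    """Back-estimate wing span and area per (specimen, wing model).

    Span comes from the induced-drag term of the published best-glide numbers:
    at best glide the induced and constant-coefficient drag are equal, so
    ``A = m g V_bg^2 / (2 * ratio)`` with ``A = k (m g)^2 / (0.5 rho pi b^2)``.
    Area comes from the stall-limited banked-turn radius
    ``r = 2 n (m/S) / (rho Cl tan(bank))``.  Estimates from different mass
    hypotheses of the same specimen agree to within ~10% and are averaged.

    These are synthetic stand-ins for unpublished wing reconstructions and are
    flagged as estimates wherever they are attached to a specimen.
    """
    phi = math.radians(bank_angle_deg)
    n_load = 1.0 / math.cos(phi) if use_load_factor else 1.0
    acc: dict[tuple[str, str], tuple[list, list]] = defaultdict(lambda: ([], []))
    for taxon, sid, model, mass, cd04, _cd05 in GLIDE_TABLE:
        v_bg, _sink, ratio, radius = cd04
        mg = mass * g
        drag_at_bg = mg / ratio            # shallow-glide total drag at best glide
        induced = drag_at_bg / 2.0         # half induced, half constant-coefficient
        b = math.sqrt(k_induced * mg ** 2 / (0.5 * rho * math.pi * induced * v_bg ** 2))
        area = 2.0 * n_load * mass / (rho * cl_max_turn * math.tan(phi) * radius)
        acc[(sid, model)][0].append(b)
        acc[(sid, model)][1].append(area)
    return {
        key: {"span_m": float(np.mean(bs)), "area_m2": float(np.mean(areas)),
              "estimated": True}
        for key, (bs, areas) in acc.items()
    }
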