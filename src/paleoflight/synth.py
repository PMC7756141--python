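"""Synthetic specimen populations for end-to-end testing and morphospace work.

The generators draw body mass (log-uniform), wing loading (uniform) and aspect
ratio (uniform), derive an exactly consistent wing geometry
(``S = m g / WL``, ``b = sqrt(Ra S)``), and back-fill skeletal segments from
simple proportional templates with optional multiplicative noise.  Only mass,
span and area matter to the downstream aerodynamics; the segments exist so the
full pipeline (ratios, sprinting, leaping) runs without error.

Each call uses one explicitly seeded ``numpy`` generator; no global state.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AeroConfig, SynthConfig
from .specimens import Specimen, SpecimenTable

#: proportional segment template relative to one forelimb length
_SEGMENT_TEMPLATE = {
    "humerus": 0.28, "ulna": 0.30, "radius": 0.29, "styliform": 0.42,
    "metacarpal_III": 0.12, "phalanges_III": 0.20,
    "metacarpal_IV": 0.16, "phalanges_IV": 0.60,
    "dpc_length": 0.06,
}


def _make_population(cfg: SynthConfig, kind: str, wing_model: str,
                     aero: AeroConfig) -> SpecimenTable:
    rng = np.random.default_rng(cfg.seed)
    lo_m, hi_m = cfg.mass_range_kg
    mass = np.exp(rng.uniform(np.log(lo_m), np.log(hi_m), cfg.n))
    loading = rng.uniform(*cfg.wing_loading_range, cfg.n)
    aspect = rng.uniform(*cfg.aspect_ratio_range, cfg.n)
    fraction = rng.uniform(*cfg.muscle_fraction_range, cfg.n)

    area = mass * aero.g / loading
    span = np.sqrt(aspect * area)
    rows = []
    for i in range(cfg.n):
        forelimb = 0.45 * span[i]
        noise = rng.lognormal(mean=0.0, sigma=cfg.noise_cv,
                              size=len(_SEGMENT_TEMPLATE) + 2) \
            if cfg.noise_cv > 0 else np.ones(len(_SEGMENT_TEMPLATE) + 2)
        segments = {name: frac * forelimb * noise[j]
                    for j, (name, frac) in enumerate(_SEGMENT_TEMPLATE.items())}
        femur = forelimb / 4.65 * noise[-2]
        tibia = 1.2 * femur * noise[-1]
        segments.update({
            "femur": femur, "tibia": tibia, "metatarsus": 0.5 * femur,
            "hindlimb_total": femur + tibia + 0.5 * femur,
            "glenoid_height": 1.1 * (femur + tibia),
        })
        rows.append(Specimen(
            taxon=f"synthetic {kind}",
            specimen_id=f"{kind}-{cfg.seed}-{i:04d}",
            mass_hypotheses_kg=(float(mass[i]),),
            flight_muscle_fraction=float(fraction[i]),
            segments_m=segments,
            wing_geometry={wing_model: {"span_m": float(span[i]),
                                        "area_m2": float(area[i]),
                                        "estimated": True}},
            meta={"drawn_wing_loading_N_m2": repr(float(loading[i])),
                  "drawn_aspect_ratio": repr(float(aspect[i]))},
        ))
    return SpecimenTable(rows=tuple(rows), provenance=f"synthetic:{kind}:seed={cfg.seed}")


def make_glider_population(cfg: SynthConfig | None = None,
                           aero: AeroConfig | None = None) -> SpecimenTable:
    """Synthetic gliders spanning the extant-glider wing-loading envelope.

    Defaults draw masses log-uniformly on 0.01-3 kg and wing loadings
    uniformly on 9-143 N m^-2; the recomputed loading of every specimen equals
    its drawn loading exactly because the geometry is derived, not sampled.
    """
    return _make_population(cfg or SynthConfig(), "glider", "MFW",
                            aero or AeroConfig())


def make_powered_flyer_population(cfg: SynthConfig | None = None,
                                  aero: AeroConfig | None = None) -> SpecimenTable:
    """Synthetic powered fliers: higher wing loadings and aspect ratios."""
    base = cfg or SynthConfig()
    flyer = base.replace(
        wing_loading_range=(30.0, 180.0) if base.wing_loading_range
        == SynthConfig().wing_loading_range else base.wing_loading_range,
        aspect_ratio_range=(7.0, 12.0) if base.aspect_ratio_range
        == SynthConfig().aspect_ratio_range else base.aspect_ratio_range,
    )
    return _make_population(flyer, "flyer", "MFW", aero or AeroConfig())


def recomputed_wing_loading(table: SpecimenTable,
                            aero: AeroConfig | None = None) -> pd.DataFrame:
    """Drawn vs recomputed wing loading per synthetic specimen."""
    cfg = aero or AeroConfig()
    records = []
    for s in table:
        model, geom = next(iter(s.wing_geometry.items()))
        records.append({
            "specimen_id": s.specimen_id,
            "drawn": float(s.meta["drawn_wing_loading_N_m2"]),
            "recomputed": s.mass_hypotheses_kg[0] * cfg.g / geom["area_m2"],
        })
    return pd.DataFrame(records)


def morphospace_summary(groups: dict[str, SpecimenTable],
                        aero: AeroConfig | None = None) -> pd.DataFrame:
    """Median and IQR of wing loading and aspect ratio per group.

    Quartiles use linear interpolation.  Raises on an empty group.
    """
    if not groups:
        raise ValueError("at least one group required")
    cfg = aero or AeroConfig()
    records = []
    for name in sorted(groups):
        table = groups[name]
        if len(table) == 0:
            raise ValueError(f"group {name!r} is empty")
        loadings, aspects = [], []
        for s in table:
            _model, geom = next(iter(s.wing_geometry.items()))
            loadings.append(s.mass_hypotheses_kg[0] * cfg.g / geom["area_m2"])
            aspects.append(geom["span_m"] ** 2 / geom["area_m2"])
        q1_wl, med_wl, q3_wl = np.percentile(loadings, [25, 50, 75])
        q1_ra, med_ra, q3_ra = np.percentile(aspects, [25, 50, 75])
        records.append({
            "group": name, "n": len(table),
            "wing_loading_median": med_wl, "wing_loading_iqr": q3_wl - q1_wl,
            "aspect_ratio_median": med_ra, "aspect_ratio_iqr": q3_ra - q1_ra,
        })
    return pd.DataFrame(records)
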