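"""Tidy result tables and per-specimen verdict summaries.

Builders return pandas DataFrames at full precision; ``render_report`` rounds
to the two-decimal precision used in the published comparison tables.  When a
specimen's wing geometry is merely estimated (fixtures) the mask policy can
replace derived aerodynamic cells with a marker string instead of printing
numbers that look like measurements.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import AeroConfig
from .glide import best_glide
from .power import power_available, powered_flight_verdict
from .specimens import SpecimenTable
from .takeoff import takeoff_analysis, wair_capability
from .wings import build_wing_model, wing_loading

MASK_TEXT = "requires measured wing geometry"


def _models_for(spec, models):
    return [m for m in (models or spec.wing_geometry.keys())
            if spec.has_geometry(m)]


def loading_table(table: SpecimenTable, config: AeroConfig | None = None,
                  models=None) -> pd.DataFrame:
    """One row per (specimen, mass, wing model): wing loading + classifications."""
    cfg = config or AeroConfig()
    records = []
    for spec in table:
        for model in _models_for(spec, models):
            planform = build_wing_model(spec, model, cfg)
            for mass in spec.mass_hypotheses_kg:
                cls = wing_loading(mass, planform, cfg)
                records.append({
                    "taxon": spec.taxon, "specimen_id": spec.specimen_id,
                    "model": model, "mass_kg": mass,
                    "wing_loading_N_m2": cls.wing_loading_N_m2,
                    "flight_possible": cls.flight_possible,
                    "in_glider_envelope": cls.in_glider_envelope,
                    "geometry_estimated": planform.estimated,
                })
    return pd.DataFrame(records)


def power_table(table: SpecimenTable, config: AeroConfig | None = None,
                models=None) -> pd.DataFrame:
    """Powered-flight comparison in the standard layout: power available (Pwr)
    and minimum mechanical power per body drag coefficient."""
    cfg = config or AeroConfig()
    records = []
    for spec in table:
        for model in _models_for(spec, models):
            for verdict in powered_flight_verdict(spec, model, cfg):
                rec = {"Taxon": spec.taxon, "Model": model,
                       "Mass (kg)": verdict.mass_kg,
                       "Pwr": verdict.P_available_W}
                for cd, (_vmp, pmin) in verdict.min_power_per_cd.items():
                    rec[f"Min Cd{cd:g}"] = pmin
                rec["geometry_estimated"] = spec.geometry_estimated(model)
                records.append(rec)
    return pd.DataFrame(records)


def glide_table(table: SpecimenTable, config: AeroConfig | None = None,
                models=None, cd_values=(0.4, 0.5)) -> pd.DataFrame:
    """Gliding comparison: best glide speed, sink, ratio, bank radius per Cd."""
    cfg = config or AeroConfig()
    records = []
    for spec in table:
        for model in _models_for(spec, models):
            planform = build_wing_model(spec, model, cfg)
            for mass in spec.mass_hypotheses_kg:
                rec = {"Taxon": spec.taxon, "Model": model, "Mass (kg)": mass}
                for cd in cd_values:
                    sol = best_glide(mass, planform, cfg, cd)
                    rec[f"Glide ms-1 Cd{cd:g}"] = sol.V_bestglide_m_s
                    rec[f"Sink ms-1 Cd{cd:g}"] = sol.sink_at_bestglide_m_s
                    rec[f"Glide ratio Cd{cd:g}"] = sol.glide_ratio
                    rec[f"Radius Cd{cd:g}"] = sol.turn_radius_m
                rec["geometry_estimated"] = planform.estimated
                records.append(rec)
    return pd.DataFrame(records)


def takeoff_table(table: SpecimenTable, config: AeroConfig | None = None,
                  models=None, cl_values=None,
                  frequency_models=("bird", "bat")) -> pd.DataFrame:
    """Launch permutations: stall vs sprint speed, flap-run time, WAIR level."""
    cfg = config or AeroConfig()
    cls = cl_values or cfg.cl_set
    records = []
    for spec in table:
        if "hindlimb_total" not in spec.segments_m:
            continue
        for model in _models_for(spec, models):
            planform = build_wing_model(spec, model, cfg)
            for mass in spec.mass_hypotheses_kg:
                for cl in cls:
                    for freq in frequency_models:
                        res = takeoff_analysis(spec, planform, cl, freq, cfg,
                                               mass_kg=mass)
                        wair = wair_capability(spec, planform, cl, freq, cfg,
                                               mass_kg=mass)
                        records.append({
                            "taxon": spec.taxon, "specimen_id": spec.specimen_id,
                            "model": model, "mass_kg": mass, "Cl": cl,
                            "frequency_model": freq,
                            "V_takeoff_m_s": res.V_takeoff_m_s,
                            "V_sprint_m_s": res.V_sprint_m_s,
                            "ratio_takeoff_sprint": res.ratio_takeoff_sprint,
                            "leap_achieves": res.leap.achieves_takeoff,
                            "t_takeoff_s": res.flaprun.t_takeoff_s,
                            "wair_lift_fraction": wair.lift_fraction_of_weight,
                            "wair_level": wair.level,
                            "geometry_estimated": planform.estimated,
                        })
    return pd.DataFrame(records)


def verdict_summary(table: SpecimenTable, config: AeroConfig | None = None,
                    models=None) -> dict:
    """Per-specimen JSON-able verdicts: loading thresholds, power budget,
    ground launch and WAIR."""
    cfg = config or AeroConfig()
    out: dict = {}
    for spec in table:
        per_model: dict = {}
        for model in _models_for(spec, models):
            planform = build_wing_model(spec, model, cfg)
            loadings = {str(m): wing_loading(m, planform, cfg).__dict__
                        for m in spec.mass_hypotheses_kg}
            verdicts = powered_flight_verdict(spec, model, cfg)
            launch = None
            if "hindlimb_total" in spec.segments_m:
                res = takeoff_analysis(spec, planform, max(cfg.cl_set),
                                       cfg.wingbeat_model, cfg)
                wair = wair_capability(spec, planform, max(cfg.cl_set),
                                       cfg.wingbeat_model, cfg)
                launch = {"flap_run_takeoff_s": res.flaprun.t_takeoff_s,
                          "leap_achieves": res.leap.achieves_takeoff,
                          "wair_level": wair.level}
            per_model[model] = {
                "geometry_estimated": planform.estimated,
                "wing_loading": loadings,
                "powered_flight_feasible_any_cd": {
                    str(v.mass_kg): v.feasible_any for v in verdicts},
                "ground_launch": launch,
            }
        out[spec.specimen_id] = {"taxon": spec.taxon, "models": per_model}
    return out


def render_report(df: pd.DataFrame, mask_estimated: bool = False,
                  decimals: int = 2) -> pd.DataFrame:
    """Round for display; optionally mask derived cells of estimated geometry."""
    out = df.copy()
    numeric = out.select_dtypes("number").columns
    out[numeric] = out[numeric].round(decimals)
    if mask_estimated and "geometry_estimated" in out.columns:
        protected = {"Mass (kg)", "mass_kg", "Cl"}
        target = [c for c in numeric if c not in protected]
        out = out.astype({c: object for c in target})
        out.loc[out["geometry_estimated"].astype(bool), target] = MASK_TEXT
    return out


def write_report(df: pd.DataFrame, path: str | Path, mask_estimated: bool = False,
                 machine: bool = False) -> Path:
    """Write a report CSV (2-decimal display) or a full-precision machine CSV."""
    path = Path(path)
    out = df if machine else render_report(df, mask_estimated=mask_estimated)
    out.to_csv(path, index=False)
    return path


def write_verdicts(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary, indent=1, sort_keys=True, default=str),
                    encoding="utf-8")
    return path
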