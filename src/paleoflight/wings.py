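"""Wing planform construction, wing loading, and anatomical ratios.

Four alternative planform hypotheses are supported for the membrane wing:

* ``MFW`` - maniraptoran-style forewing only (membrane behind the arm,
  supported by the styliform element);
* ``BBW`` - bat-style membrane continuing to the ankle (fore + hind wing);
* ``PTW`` - pterosaur-style membrane attaching at the knee;
* ``FRW`` - frog-style webbing restricted to the spread manual digits.

When a specimen carries explicit wing geometry it is passed through; otherwise
the planform is built as a polygon over documented anatomical anchor points
(shoulder, elbow, wrist, styliform tip, digit IV tip, plus hindlimb anchors for
BBW/PTW) and its area computed exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from shapely.geometry import Polygon

from .config import AeroConfig
from .specimens import SchemaError, Specimen, ValidationError

WING_MODELS = ("MFW", "BBW", "PTW", "FRW")


@dataclass(frozen=True)
class WingPlanform:
    """A reconstructed lifting surface: total span, total area, aspect ratio."""

    model: str
    span_b_m: float
    area_S_m2: float
    estimated: bool = False

    def __post_init__(self) -> None:
        if self.model not in WING_MODELS:
            raise ValueError(f"unknown wing model {self.model!r}")
        if self.span_b_m <= 0 or self.area_S_m2 <= 0:
            raise ValueError("span and area must be > 0")

    @property
    def aspect_ratio_Ra(self) -> float:
        return self.span_b_m ** 2 / self.area_S_m2


@dataclass(frozen=True)
class LoadingClassification:
    wing_loading_N_m2: float
    flight_possible: bool       # <= 245 N m^-2
    in_glider_envelope: bool    # within [9, 143] N m^-2 (inclusive)


def polygon_area(points) -> float:
    """Area of a simple polygon given as (x, y) vertex pairs."""
    poly = Polygon(points)
    if not poly.is_valid:
        raise ValueError("planform polygon is self-intersecting or degenerate")
    return float(poly.area)


# ---------------------------------------------------------------------------
# planform templates
#
# Coordinates: y spanwise from the glenoid outward, x chordwise (positive aft).
# The arm is treated as fully extended along the leading edge, which matches
# the maximal-extension convention of the published reconstructions.

def _anchors(spec: Specimen, model: str) -> dict[str, float]:
    needed = {
        "MFW": ("humerus", "ulna", "styliform", "metacarpal_IV", "phalanges_IV"),
        "BBW": ("humerus", "ulna", "styliform", "metacarpal_IV", "phalanges_IV",
                "hindlimb_total"),
        "PTW": ("humerus", "ulna", "styliform", "metacarpal_IV", "phalanges_IV",
                "femur", "tibia"),
        "FRW": ("metacarpal_IV", "phalanges_IV", "metacarpal_III", "phalanges_III"),
    }[model]
    missing = [name for name in needed if name not in spec.segments_m]
    if missing:
        raise SchemaError(
            f"{spec.specimen_id}: wing model {model} needs segments {missing}")
    return {name: spec.segments_m[name] for name in needed}


def _template_polygon(spec: Specimen, model: str) -> list[tuple[float, float]]:
    seg = _anchors(spec, model)
    if model == "FRW":
        # webbing spread between digits III and IV only: a triangle from the
        # wrist to the two digit tips, chordwise separation set by digit spread
        d4 = seg["metacarpal_IV"] + seg["phalanges_IV"]
        d3 = seg["metacarpal_III"] + seg["phalanges_III"]
        spread = 0.5 * d3   # chordwise gap between spread digits at the tips
        return [(0.0, 0.0), (0.0, d4), (spread, d3)]
    shoulder_y = 0.0
    elbow_y = seg["humerus"]
    wrist_y = elbow_y + seg["ulna"]
    tip_y = wrist_y + seg["metacarpal_IV"] + seg["phalanges_IV"]
    sty = seg["styliform"]       # styliform juts aft from the wrist
    # leading edge runs x=0 from shoulder to digit tip; trailing edge returns
    # through the styliform tip to the root chord
    if model == "MFW":
        root_chord = 0.6 * sty   # membrane tapers out near the body
    elif model == "BBW":
        root_chord = seg["hindlimb_total"]   # membrane reaches the ankle
    else:  # PTW
        root_chord = seg["femur"] + seg["tibia"]   # membrane reaches the knee
    return [(0.0, shoulder_y), (0.0, tip_y), (sty, wrist_y), (root_chord, shoulder_y)]


def build_wing_model(spec: Specimen, model: str, config: AeroConfig | None = None,
                     body_width_m: float | None = None) -> WingPlanform:
    """Planform for ``model``: explicit geometry pass-through, else template.

    The template area is the polygon area of one wing doubled, plus a body
    strip (body width x mean chord) for MFW/BBW/PTW; span is twice the
    spanwise extent plus the body width.  ``body_width_m`` defaults to half
    the humerus length (a crude shoulder-breadth proxy).
    """
    if model not in WING_MODELS:
        raise ValueError(f"unknown wing model {model!r}")
    if spec.has_geometry(model):
        geom = spec.wing_geometry[model]
        return WingPlanform(model=model, span_b_m=geom["span_m"],
                            area_S_m2=geom["area_m2"],
                            estimated=bool(geom.get("estimated", False)))
    points = _template_polygon(spec, model)
    one_wing = polygon_area(points)
    semispan = max(y for _x, y in points)
    if body_width_m is None:
        body_width_m = 0.0 if model == "FRW" else 0.5 * spec.segment("humerus")
    mean_chord = one_wing / semispan
    body_strip = 0.0 if model == "FRW" else body_width_m * mean_chord
    return WingPlanform(model=model,
                        span_b_m=2.0 * semispan + body_width_m,
                        area_S_m2=2.0 * one_wing + body_strip,
                        estimated=True)


def wing_loading(mass_kg: float, planform: WingPlanform,
                 config: AeroConfig | None = None) -> LoadingClassification:
    """Weight per unit lifting area, classified against flight thresholds.

    ``flight_possible`` applies the 245 N m^-2 ceiling for any form of flight;
    ``in_glider_envelope`` checks the 9-143 N m^-2 range spanned by extant
    gliders.  Both bounds are inclusive.
    """
    if mass_kg <= 0:
        raise ValidationError("mass must be > 0")
    cfg = config or AeroConfig()
    wl = mass_kg * cfg.g / planform.area_S_m2
    lo, hi = cfg.glider_envelope
    return LoadingClassification(
        wing_loading_N_m2=wl,
        flight_possible=wl <= cfg.wing_loading_flight_max,
        in_glider_envelope=lo <= wl <= hi,
    )


# ---------------------------------------------------------------------------
# anatomical ratios

def anatomical_ratios(spec: Specimen, include_manus_in_forelimb: bool = False) -> dict:
    """Dimensionless skeletal ratios used as locomotor signals.

    Returns only the ratios whose segments are present:

    * ``styliform_fraction`` - styliform / (humerus + ulna + styliform);
    * ``dpc_fraction`` - deltopectoral crest / humerus (flight-muscle proxy);
    * ``forelimb_femur`` - (humerus + ulna + styliform [+ manus]) / femur;
    * ``crural_index`` - tibia / femur (arboreality signal);
    * ``phalangeal_index_<digit>`` - non-ungual phalanx lengths / metacarpal.

    A zero-length denominator raises :class:`ValidationError`; a missing
    segment simply omits that ratio.
    """
    seg = spec.segments_m

    def have(*names: str) -> bool:
        return all(n in seg for n in names)

    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            raise ValidationError(f"{spec.specimen_id}: zero denominator for {what}")
        return num / den

    out: dict[str, float] = {}
    if have("humerus", "ulna", "styliform"):
        forelimb = seg["humerus"] + seg["ulna"] + seg["styliform"]
        out["styliform_fraction"] = ratio(seg["styliform"], forelimb,
                                          "styliform_fraction")
        if have("femur"):
            if include_manus_in_forelimb and have("metacarpal_IV", "phalanges_IV"):
                forelimb = forelimb + seg["metacarpal_IV"] + seg["phalanges_IV"]
            out["forelimb_femur"] = ratio(forelimb, seg["femur"], "forelimb_femur")
    if have("dpc_length", "humerus"):
        out["dpc_fraction"] = ratio(seg["dpc_length"], seg["humerus"], "dpc_fraction")
    if have("tibia", "femur"):
        out["crural_index"] = ratio(seg["tibia"], seg["femur"], "crural_index")
    for digit in ("II", "III", "IV"):
        if have(f"metacarpal_{digit}", f"phalanges_{digit}"):
            out[f"phalangeal_index_{digit}"] = ratio(
                seg[f"phalanges_{digit}"], seg[f"metacarpal_{digit}"],
                f"phalangeal_index_{digit}")
    return out
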