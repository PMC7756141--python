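"""Specimen data model, validation, readers/writers and built-in fixtures.

A :class:`Specimen` is one fossil (or extant) individual: its mass hypotheses,
flight-muscle fraction, named skeletal segment lengths, and optional per-wing-
model geometry.  All values are SI after loading (m, kg); loaders convert from
mm/g when a row's ``length_unit``/``mass_unit`` columns say so.

The built-in fixtures carry the published mass permutations for *Yi qi*,
*Ambopteryx*, *Archaeopteryx* (Berlin) and *Microraptor* plus segment lengths
that reproduce the published anatomical ratios.  Segment lengths and wing
geometry are synthetic estimates (flagged), because the measured wing
reconstructions were published only in supplementary material; a documented
override file can inject measured values.
"""
from __future__ import annotations

import csv
import hashlib
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import published

WING_MODELS = ("MFW", "BBW", "PTW", "FRW")
#: wing models whose lifting surface must be wider than a line (aspect ratio > 1
#: would fail only for degenerate geometry); the frog-style webbing is exempt.
_AR_CHECKED_MODELS = ("MFW", "BBW", "PTW")


class SchemaError(ValueError):
    """A required column/key is missing or malformed."""


class ValidationError(ValueError):
    """A specimen violates a domain invariant."""


@dataclass(frozen=True)
class Specimen:
    taxon: str
    specimen_id: str
    mass_hypotheses_kg: tuple[float, ...]
    flight_muscle_fraction: float = 0.10
    segments_m: Mapping[str, float] = field(default_factory=dict)
    wing_geometry: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    notes: str = ""
    segments_placeholder: bool = False
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass_hypotheses_kg",
                           tuple(float(m) for m in self.mass_hypotheses_kg))
        object.__setattr__(self, "segments_m", dict(self.segments_m))
        object.__setattr__(self, "wing_geometry",
                           {k: dict(v) for k, v in self.wing_geometry.items()})
        object.__setattr__(self, "meta", dict(self.meta))
        self.validate()

    def validate(self) -> None:
        if not self.specimen_id:
            raise SchemaError("specimen_id is required")
        if not self.mass_hypotheses_kg:
            raise SchemaError(f"{self.specimen_id}: at least one mass hypothesis required")
        masses = self.mass_hypotheses_kg
        if any(m <= 0 for m in masses):
            raise ValidationError(f"{self.specimen_id}: masses must be > 0")
        if list(masses) != sorted(set(masses)):
            raise ValidationError(
                f"{self.specimen_id}: mass hypotheses must be ascending and distinct")
        if not 0 < self.flight_muscle_fraction <= 1:
            raise ValidationError(
                f"{self.specimen_id}: flight_muscle_fraction must lie in (0, 1]")
        for name, value in self.segments_m.items():
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"{self.specimen_id}: segment {name!r} must be a positive length")
        for model, geom in self.wing_geometry.items():
            if model not in WING_MODELS:
                raise SchemaError(f"{self.specimen_id}: unknown wing model {model!r}")
            span, area = geom.get("span_m"), geom.get("area_m2")
            if span is None or area is None:
                raise SchemaError(
                    f"{self.specimen_id}: wing geometry for {model} needs span_m and area_m2")
            if span <= 0 or area <= 0:
                raise ValidationError(
                    f"{self.specimen_id}: wing geometry for {model} must be positive")
            if model in _AR_CHECKED_MODELS and area >= span ** 2:
                raise ValidationError(
                    f"{self.specimen_id}: {model} area {area} >= span^2 {span ** 2}"
                    " (aspect ratio must exceed 1)")

    def segment(self, name: str) -> float:
        try:
            return self.segments_m[name]
        except KeyError:
            raise SchemaError(f"{self.specimen_id}: segment {name!r} not recorded") from None

    def has_geometry(self, model: str) -> bool:
        return model in self.wing_geometry

    def geometry_estimated(self, model: str) -> bool:
        return bool(self.wing_geometry.get(model, {}).get("estimated", False))


@dataclass(frozen=True)
class SpecimenTable:
    rows: tuple[Specimen, ...]
    provenance: str = "in-memory"
    checksum: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        ids = [s.specimen_id for s in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate specimen_id in table: {dupes}")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, specimen_id: str) -> Specimen:
        for s in self.rows:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_specimen_to_record(s) for s in self.rows])


# ---------------------------------------------------------------------------
# serialisation

_CORE_COLUMNS = ("taxon", "specimen_id", "mass_kg_list", "muscle_fraction")


def _specimen_to_record(s: Specimen) -> dict:
    rec: dict = {
        "taxon": s.taxon,
        "specimen_id": s.specimen_id,
        "mass_kg_list": ";".join(repr(m) for m in s.mass_hypotheses_kg),
        "muscle_fraction": repr(s.flight_muscle_fraction),
        "notes": s.notes,
        "segments_placeholder": int(s.segments_placeholder),
    }
    for name, value in sorted(s.segments_m.items()):
        rec[f"seg:{name}_m"] = repr(float(value))
    for model, geom in sorted(s.wing_geometry.items()):
        rec[f"wing:{model}_span_m"] = repr(float(geom["span_m"]))
        rec[f"wing:{model}_area_m2"] = repr(float(geom["area_m2"]))
        rec[f"wing:{model}_estimated"] = int(bool(geom.get("estimated", False)))
    rec.update(s.meta)
    return rec


def _record_to_specimen(rec: Mapping[str, str], row_id: str) -> Specimen:
    rec = {k: v for k, v in rec.items() if v not in (None, "")}
    for col in ("taxon", "specimen_id", "mass_kg_list"):
        if col not in rec:
            raise SchemaError(f"row {row_id}: missing required column {col!r}")
    length_scale = 1.0
    mass_scale = 1.0
    unit = str(rec.pop("length_unit", "m")).lower()
    if unit == "mm":
        length_scale = 1e-3
    elif unit != "m":
        raise SchemaError(f"row {row_id}: unsupported length_unit {unit!r}")
    unit = str(rec.pop("mass_unit", "kg")).lower()
    if unit == "g":
        mass_scale = 1e-3
    elif unit != "kg":
        raise SchemaError(f"row {row_id}: unsupported mass_unit {unit!r}")

    try:
        masses = tuple(float(x) * mass_scale
                       for x in str(rec.pop("mass_kg_list")).split(";") if x)
    except ValueError as exc:
        raise SchemaError(f"row {row_id}: malformed mass_kg_list ({exc})") from None
    segments, geometry, meta = {}, {}, {}
    estimated_flags = {}
    for key, value in list(rec.items()):
        if key.startswith("seg:") and key.endswith("_m"):
            segments[key[4:-2]] = float(value) * length_scale
        elif key.startswith("wing:"):
            body = key[5:]
            if body.endswith("_span_m"):
                geometry.setdefault(body[:-7], {})["span_m"] = float(value) * length_scale
            elif body.endswith("_area_m2"):
                geometry.setdefault(body[:-8], {})["area_m2"] = \
                    float(value) * length_scale ** 2
            elif body.endswith("_estimated"):
                estimated_flags[body[:-10]] = bool(int(float(value)))
            else:
                raise SchemaError(f"row {row_id}: unrecognised wing column {key!r}")
        elif key in ("taxon", "specimen_id", "notes", "muscle_fraction",
                     "segments_placeholder"):
            continue
        else:
            meta[key] = value
    for model, flag in estimated_flags.items():
        if model in geometry:
            geometry[model]["estimated"] = flag
    return Specimen(
        taxon=str(rec["taxon"]),
        specimen_id=str(rec["specimen_id"]),
        mass_hypotheses_kg=masses,
        flight_muscle_fraction=float(rec.get("muscle_fraction", 0.10)),
        segments_m=segments,
        wing_geometry=geometry,
        notes=str(rec.get("notes", "")),
        segments_placeholder=bool(int(float(rec.get("segments_placeholder", 0)))),
        meta=meta,
    )


def load_specimens(path: str | Path, format: str | None = None) -> SpecimenTable:
    """Load a specimen table from CSV or JSON (auto-detected from suffix).

    Raises :class:`SchemaError` for missing required fields and
    :class:`ValidationError` (naming the row) for domain violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    text = path.read_text(encoding="utf-8")
    checksum = hashlib.sha256(text.encode()).hexdigest()
    if fmt == "csv":
        records = list(csv.DictReader(io.StringIO(text)))
    elif fmt == "json":
        records = json.loads(text)
        if not isinstance(records, list):
            raise SchemaError("JSON specimen file must contain a list of records")
    else:
        raise ValueError(f"unsupported specimen format {fmt!r}")
    rows = [_record_to_specimen(rec, row_id=str(i)) for i, rec in enumerate(records)]
    return SpecimenTable(rows=tuple(rows), provenance=str(path), checksum=checksum)


def save_specimens(table: SpecimenTable | Iterable[Specimen], path: str | Path,
                   format: str | None = None) -> Path:
    """Write the table in the CSV/JSON dialect understood by :func:`load_specimens`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = list(table)
    records = [_specimen_to_record(s) for s in rows]
    if fmt == "csv":
        columns: list[str] = []
        for rec in records:
            for key in rec:
                if key not in columns:
                    columns.append(key)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns)
            writer.writeheader()
            writer.writerows(records)
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unsupported specimen format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# built-in fixtures

def _yi_segments() -> dict[str, float]:
    # reproduces the published ratios: styliform 42% of (humerus+ulna+styliform),
    # forelimb 4.65x femur, deltopectoral crest 19% of humerus, manual phalangeal
    # index 1.7 (digit III) and 4.35 (digit IV)
    humerus, ulna, styliform = 0.0680, 0.0750, 0.10353
    femur = (humerus + ulna + styliform) / 4.65
    return {
        "humerus": humerus, "ulna": ulna, "radius": 0.0730,
        "styliform": styliform,
        "metacarpal_III": 0.0300, "phalanges_III": 0.0510,
        "metacarpal_IV": 0.0400, "phalanges_IV": 0.1740,
        "dpc_length": 0.19 * humerus,
        "femur": femur, "tibia": 0.0625, "metatarsus": 0.0285,
        "hindlimb_total": femur + 0.0625 + 0.0285,
        "glenoid_height": 0.16,
    }


def _ambopteryx_segments() -> dict[str, float]:
    femur = 0.0400
    forelimb = 4.65 * femur           # styliform is 32% of it
    styliform = 0.32 * forelimb
    humerus = 0.0600
    ulna = forelimb - styliform - humerus
    return {
        "humerus": humerus, "ulna": ulna, "radius": 0.0580,
        "styliform": styliform,
        "metacarpal_IV": 0.0350, "phalanges_IV": 0.1300,
        "dpc_length": 0.22 * humerus,
        "femur": femur, "tibia": 0.0520, "metatarsus": 0.0245,
        "hindlimb_total": femur + 0.0520 + 0.0245,
        "glenoid_height": 0.13,
    }


_PLACEHOLDER_NOTE = ("segment lengths and wing geometry are synthetic estimates "
                     "(geometry back-estimated from published glide performance); "
                     "supply measured values via an override file")


def builtin_fixtures(override_path: str | Path | None = None) -> SpecimenTable:
    """Built-in comparative specimens with published mass permutations.

    Wing spans/areas are estimates inverted from published glide performance
    (:func:`paleoflight.published.estimate_geometry`) and carry
    ``estimated: True``; segment lengths are plausible synthetic values that
    reproduce the published anatomical ratios, flagged via
    ``segments_placeholder``.  Pass ``override_path`` (CSV/JSON in the standard
    dialect) to replace any fixture wholesale by matching ``specimen_id``.
    """
    geom = published.estimate_geometry()

    def wings(sid: str, *models: str) -> dict:
        return {m: dict(geom[(sid, m)]) for m in models if (sid, m) in geom}

    rows = [
        Specimen(
            taxon="Yi qi", specimen_id="STM 31-2",
            mass_hypotheses_kg=(0.38, 0.45, 0.70),
            segments_m=_yi_segments(),
            wing_geometry=wings("STM 31-2", "MFW", "BBW"),
            notes="radiale angle ~40 deg (early-paravian model) / ~50 deg "
                  "(pennaraptoran model); " + _PLACEHOLDER_NOTE,
            segments_placeholder=True,
        ),
        Specimen(
            taxon="Ambopteryx longibrachium", specimen_id="STM 0-144",
            mass_hypotheses_kg=(0.23, 0.31, 0.38),
            segments_m=_ambopteryx_segments(),
            wing_geometry=wings("STM 0-144", "MFW", "BBW"),
            notes=_PLACEHOLDER_NOTE,
            segments_placeholder=True,
        ),
        Specimen(
            taxon="Archaeopteryx lithographica", specimen_id="Berlin",
            mass_hypotheses_kg=(0.20,),
            segments_m={
                "humerus": 0.0630, "ulna": 0.0560, "dpc_length": 0.34 * 0.0630,
                "femur": 0.0530, "tibia": 0.0710, "metatarsus": 0.0330,
                "hindlimb_total": 0.157, "glenoid_height": 0.15,
            },
            wing_geometry=wings("Berlin", "MFW"),
            notes=_PLACEHOLDER_NOTE, segments_placeholder=True,
        ),
        Specimen(
            taxon="Microraptor gui", specimen_id="BMNHC PH881",
            mass_hypotheses_kg=(0.18, 0.24),
            segments_m={
                "humerus": 0.0680, "ulna": 0.0650, "dpc_length": 0.29 * 0.0680,
                "femur": 0.0750, "tibia": 0.0980, "metatarsus": 0.0450,
                "hindlimb_total": 0.218, "glenoid_height": 0.17,
            },
            wing_geometry=wings("BMNHC PH881", "MFW"),
            notes=_PLACEHOLDER_NOTE, segments_placeholder=True,
        ),
        Specimen(
            taxon="Microraptor gui", specimen_id="IVPP V13352",
            mass_hypotheses_kg=(0.50, 0.95),
            segments_m={
                "humerus": 0.0880, "ulna": 0.0830, "dpc_length": 0.29 * 0.0880,
                "femur": 0.0980, "tibia": 0.1280, "metatarsus": 0.0580,
                "hindlimb_total": 0.284, "glenoid_height": 0.20,
            },
            wing_geometry=wings("IVPP V13352", "MFW"),
            notes=_PLACEHOLDER_NOTE, segments_placeholder=True,
        ),
        # hindlimb-only comparators for the crural-index contrast
        Specimen(
            taxon="Epidendrosaurus ninchengensis", specimen_id="IVPP V12653",
            mass_hypotheses_kg=(0.025,),
            segments_m={"femur": 0.0129, "tibia": 1.17 * 0.0129},
            notes="juvenile; hindlimb-only fixture; " + _PLACEHOLDER_NOTE,
            segments_placeholder=True,
        ),
        Specimen(
            taxon="Epidexipteryx hui", specimen_id="IVPP V15471",
            mass_hypotheses_kg=(0.22,),
            segments_m={"femur": 0.0539, "tibia": 1.25 * 0.0539},
            notes="hindlimb-only fixture; " + _PLACEHOLDER_NOTE,
            segments_placeholder=True,
        ),
    ]
    table = SpecimenTable(rows=tuple(rows), provenance="builtin")
    if override_path is not None:
        overrides = {s.specimen_id: s for s in load_specimens(override_path)}
        merged = tuple(overrides.pop(s.specimen_id, s) for s in table.rows)
        table = SpecimenTable(rows=merged + tuple(overrides.values()),
                              provenance=f"builtin+{override_path}")
    return table
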