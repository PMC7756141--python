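"""Model constants and run configuration.

All quantities are SI (m, kg, s, N, W, rad) unless a field name says otherwise.
``AeroConfig`` gathers every tunable aerodynamic and physiological constant so
the same specimen can be re-analysed under different assumptions; ``SynthConfig``
drives the synthetic-population generators.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class AeroConfig:
    """Environment and model constants for the flight-feasibility pipeline.

    Defaults follow the standard fixed-wing / flapping-flight theory for
    vertebrate fliers.  The muscle burst-power allometry
    ``s(m) = muscle_power_coeff * m ** muscle_power_exp`` (W per kg of flight
    muscle) is a least-squares calibration against published power-availability
    estimates for 0.18-0.95 kg paravians and scansoriopterygids; see
    :func:`paleoflight.power.fit_muscle_power_allometry`.
    """

    # environment
    rho_air: float = 1.225          # air density, kg m^-3
    g: float = 9.81                 # gravitational acceleration, m s^-2

    # drag / lift model
    k_induced: float = 1.2          # induced-power (induced-drag) factor
    cd_body_set: tuple[float, ...] = (0.1, 0.4, 0.5)   # body drag coefficients
    cl_set: tuple[float, ...] = (1.0, 1.5)             # lift coefficients
    cpro: float = 8.4               # profile-power constant (divided by aspect ratio)
    cd_profile_glide: float = 0.014  # wing profile drag coefficient in gliding
    frontal_area_coeff: float = 0.00813  # body frontal area = coeff * m^exp, m^2
    frontal_area_exp: float = 0.666

    # flight muscle
    muscle_power_coeff: float = 107.2   # W per kg muscle at 1 kg body mass
    muscle_power_exp: float = -0.26
    lift_capacity_coeff: float = 84.0   # N per kg muscle at 1 kg body mass
    lift_capacity_exp: float = -0.26

    # flapping
    wingbeat_model: str = "bird"        # "bird" or "bat"
    bat_frequency_factor: float = 0.65  # bat wingbeat frequency relative to bird
    flap_amplitude_rad: float = 1.2     # total stroke amplitude (tip-to-tip angle)
    stroke_plane_deg: float = 62.0      # stroke plane tilt from horizontal

    # terrestrial launch
    sprint_coeff_a: float = 12.5        # v = a * leg^p * m^q  (m s^-1)
    sprint_exp_p: float = 0.5
    sprint_exp_q: float = 0.0
    leg_accel_max: float = 1.0          # sustained running acceleration, m s^-2
    leap_coeff: float = 2.0             # launch speed = c * sqrt(g * hip height)
    cd_body_takeoff: float = 0.4        # body Cd used in launch simulations
    dt: float = 0.01                    # integration step, s
    horizon_s: float = 20.0             # flap-run simulation horizon, s

    # wing-assisted incline running
    wair_speed: float = 1.5             # reference run speed, m s^-1
    wair_level1_fraction: float = 0.2   # lift/weight needed for level I
    wair_level2_fraction: float = 0.5   # lift/weight needed for level II

    # turning / thresholds
    cl_max_turn: float = 1.5
    bank_angle_deg: float = 24.0
    use_load_factor: bool = True        # n = 1/cos(bank); False sets n = 1
    wing_loading_flight_max: float = 245.0   # N m^-2, any-flight ceiling
    glider_envelope: tuple[float, float] = (9.0, 143.0)  # N m^-2, extant gliders

    def __post_init__(self) -> None:
        for name in ("rho_air", "g", "k_induced", "cpro", "frontal_area_coeff",
                     "muscle_power_coeff", "lift_capacity_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AeroConfig.{name} must be > 0")
        if not self.cd_body_set or not self.cl_set:
            raise ValueError("cd_body_set and cl_set must be non-empty")
        if any(c <= 0 for c in self.cd_body_set) or any(c <= 0 for c in self.cl_set):
            raise ValueError("drag and lift coefficients must be > 0")
        if self.wingbeat_model not in ("bird", "bat"):
            raise ValueError("wingbeat_model must be 'bird' or 'bat'")
        if not 0 < self.bank_angle_deg < 90:
            raise ValueError("bank_angle_deg must lie in (0, 90)")

    def replace(self, **kwargs) -> "AeroConfig":
        return dataclasses.replace(self, **kwargs)

    def frontal_area(self, mass_kg: float) -> float:
        """Body frontal area (m^2) from the standard allometry."""
        return self.frontal_area_coeff * mass_kg ** self.frontal_area_exp

    def muscle_specific_power(self, mass_kg: float) -> float:
        """Burst mechanical power per kg of flight muscle, W/kg."""
        return self.muscle_power_coeff * mass_kg ** self.muscle_power_exp

    def lift_capacity(self, mass_kg: float) -> float:
        """Burst lift per kg of flight muscle, N/kg."""
        return self.lift_capacity_coeff * mass_kg ** self.lift_capacity_exp


@dataclass(frozen=True)
class SynthConfig:
    """Parameters for the synthetic specimen generators.

    Defaults span the wing-loading envelope reported for extant gliders
    (9-143 N m^-2) and glider body masses up to ~3 kg.
    """

    seed: int = 0
    n: int = 100
    mass_range_kg: tuple[float, float] = (0.01, 3.0)        # log-uniform
    wing_loading_range: tuple[float, float] = (9.0, 143.0)  # uniform, N m^-2
    muscle_fraction_range: tuple[float, float] = (0.08, 0.12)
    aspect_ratio_range: tuple[float, float] = (4.0, 8.0)
    noise_cv: float = 0.05   # relative noise on back-filled segment lengths

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("mass_range_kg", "wing_loading_range",
                     "muscle_fraction_range", "aspect_ratio_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"SynthConfig.{name} must be a positive interval")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


def _coerce(value, template):
    if isinstance(template, bool):
        return bool(value)
    if isinstance(template, tuple):
        return tuple(type(template[0])(v) for v in value)
    return type(template)(value)


def load_config(path: str | Path, cls=AeroConfig, **overrides):
    """Build a config from a YAML / ``key: value`` file, then apply overrides.

    Precedence: explicit overrides > file entries > dataclass defaults.
    Unknown keys raise, naming the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain key-value pairs")
    defaults = cls()
    known = {f.name: getattr(defaults, f.name) for f in dataclasses.fields(cls)}
    merged = {}
    for key, value in raw.items():
        if key not in known:
            raise KeyError(f"unknown config key {key!r} for {cls.__name__}")
        merged[key] = _coerce(value, known[key])
    merged.update(overrides)
    return cls(**merged)
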