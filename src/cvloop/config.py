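"""Configuration loading with unit normalization.

Configuration files are YAML with sections ``circulation``, ``muscle``,
``protocol``, ``integrator``, ``fixtures`` and a top-level ``seed``.  Every
physical quantity may be given either as a bare number (interpreted as SI)
or as a string with an SI-prefixed unit, e.g. ``"175 GPa·s/m^3"``,
``"24 mL"``, ``"50 us"``.  All quantities are normalized to SI (Pa, m³, s)
on load.  An empty file (or no file) yields the package defaults: the
rat-scale circulation parameter set and the reference trabecula geometry.

Unknown keys are rejected by name, and inconsistent volume partitions
(V_t ≠ V_s + V_u) fail validation rather than being silently repaired.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core_model import CirculationParameters, InvalidParameterError
from .muscle_models import (
    MuscleGeometry,
    TwitchActivation,
    VirtualTrabecula,
    ellipse_csa,
    volume_to_radius,
)

__all__ = [
    "RunConfig",
    "IntegratorSettings",
    "ProtocolSettings",
    "FixtureSettings",
    "load_config",
    "save_config",
    "parse_quantity",
    "default_muscle",
    "ConfigError",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_PREFIXES = {
    "G": 1e9,
    "M": 1e6,
    "k": 1e3,
    "m": 1e-3,
    "u": 1e-6,
    "n": 1e-9,
    "p": 1e-12,
    "f": 1e-15,
}

# Accepted base-unit spellings per quantity kind, after normalization
# ('·'→'.', superscripts→'^n', 'µ'→'u', whitespace stripped).  The factor
# maps the spelled unit to SI.  The compliance row also accepts the
# transposed spelling "m^-3.Pa" (read as m³/Pa), which appears in tabulated
# parameter sets.
_BASE_UNITS: dict[str, dict[str, float]] = {
    "resistance": {"Pa.s.m^-3": 1.0, "Pa.s/m^3": 1.0},
    "compliance": {"m^3.Pa^-1": 1.0, "m^3/Pa": 1.0, "m^-3.Pa": 1.0},
    "elastance": {"Pa.m^-3": 1.0, "Pa/m^3": 1.0},
    "pressure": {"Pa": 1.0},
    "volume": {"m^3": 1.0, "L": 1e-3, "l": 1e-3},
    "length": {"m": 1.0},
    "area": {"m^2": 1.0},
    "time": {"s": 1.0},
    "frequency": {"Hz": 1.0},
    "voltage": {"V": 1.0},
    "dimensionless": {"": 1.0},
}

_NUM_RE = re.compile(r"^\s*([+-]?[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*(.*)$")


def _normalize_unit(u: str) -> str:
    u = u.strip()
    u = u.replace("·", ".").replace("⋅", ".").replace("µ", "u").replace("μ", "u")
    u = u.replace("⁻", "^-").replace("²", "^2").replace("³", "^3")
    u = re.sub(r"\s+", "", u)
    return u


def parse_quantity(value, kind: str) -> float:
    """Parse a config value of the given physical kind into SI units.

    Numbers pass through unchanged (assumed SI); strings must be
    ``"<number> <unit>"`` where the unit is an optionally SI-prefixed
    spelling accepted for ``kind`` (prefix applies to the leading unit
    token, so ``pm^3/Pa`` is 1e-12 m³/Pa and ``mL`` is 1e-6 m³).
    """
    if kind not in _BASE_UNITS:
        raise ConfigError(f"unknown quantity kind {kind!r}")
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise ConfigError(f"cannot parse {value!r} as a {kind}")
    m = _NUM_RE.match(value)
    if not m:
        raise ConfigError(f"cannot parse {value!r} as a {kind}")
    num = float(m.group(1))
    unit = _normalize_unit(m.group(2))
    table = _BASE_UNITS[kind]
    if unit in table:
        return num * table[unit]
    if unit and unit[0] in _PREFIXES and unit[1:] in table:
        base = unit[1:]
        # For geometric units the prefix binds inside the power (mm^2 is
        # (1e-3 m)^2); for compound quantities like compliance the printed
        # prefix scales the whole value (nm^3/Pa means 1e-9 m^3/Pa).
        power = 1
        if kind == "area" and base.startswith("m^2"):
            power = 2
        elif kind == "volume" and base == "m^3":
            power = 3
        return num * _PREFIXES[unit[0]] ** power * table[base]
    raise ConfigError(
        f"unit {m.group(2)!r} not recognized for {kind} in {value!r}"
    )


@dataclass(frozen=True)
class IntegratorSettings:
    dt: float = 5.0e-5          # real-time tick [s]; 20 kHz by default
    n_cycles: int = 150
    ss_tol: float = 1.0e-10     # steady-state volume tolerance [m^3]

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_cycles < 1 or self.ss_tol <= 0:
            raise ConfigError("integrator settings must be positive")


@dataclass(frozen=True)
class ProtocolSettings:
    kind: str = "closed-loop"
    r_sys_grid: tuple[float, ...] = (
        800e9, 500e9, 300e9, 175e9, 115e9, 50e9, 30e9
    )
    edl: float = 1.0
    isometric_length_rel: float = 1.0
    restretch_duration: float = 0.150
    restretch_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in (
            "closed-loop", "windkessel", "isometric", "sweep", "insilico"
        ):
            raise ConfigError(f"unknown protocol kind {self.kind!r}")


@dataclass(frozen=True)
class FixtureSettings:
    n_twitches: int = 6
    repeats: int = 2
    noise_sd: float = 0.0        # thermopile voltage noise SD [V]
    drift_rate: float = 0.0      # slow drift [V/s]
    sample_rate: float = 100.0   # voltage trace sampling [Hz]
    sensitivity: float = 4000.0  # thermopile sensitivity [V/W]
    dt: float = 2.5e-4           # integration tick for fixture runs [s]


@dataclass
class RunConfig:
    circulation: CirculationParameters = field(default_factory=CirculationParameters)
    muscle: VirtualTrabecula = None  # type: ignore[assignment]
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)
    integrator: IntegratorSettings = field(default_factory=IntegratorSettings)
    fixtures: FixtureSettings = field(default_factory=FixtureSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.muscle is None:
            self.muscle = default_muscle(self.circulation)

    def to_dict(self) -> dict:
        m = self.muscle
        return {
            "circulation": asdict(self.circulation)
            | {"unstressed_split": list(self.circulation.unstressed_split)},
            "muscle": {
                "A": m.geometry.A,
                "L_o": m.geometry.L_o,
                "h": m.geometry.h,
                "r_0": m.geometry.r_0,
                "d_major": m.geometry.d_major,
                "d_minor": m.geometry.d_minor,
                "sigma_max": m.sigma_max,
                "slack_rel": m.slack_rel,
                "passive_a": m.passive_a,
                "passive_b": m.passive_b,
                "heat_coeff": m.heat_coeff,
                "activation": {
                    "freq": m.activation.freq,
                    "tau_rise": m.activation.tau_rise,
                    "tau_decay": m.activation.tau_decay,
                },
            },
            "protocol": asdict(self.protocol)
            | {"r_sys_grid": list(self.protocol.r_sys_grid)},
            "integrator": asdict(self.integrator),
            "fixtures": asdict(self.fixtures),
            "seed": self.seed,
        }

    def digest(self) -> str:
        """Stable hash of the resolved configuration, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def default_muscle(circulation: CirculationParameters | None = None) -> VirtualTrabecula:
    """The reference trabecula: mean dimensions of the study preparations
    (392 × 376 µm diameters, L₀ = 3.56 mm) with the reference ventricular
    radius derived from the initial LV volume, so that at V_LV_init the
    commanded length is exactly L₀."""
    circulation = circulation or CirculationParameters()
    geom = MuscleGeometry.from_diameters(
        d_major=392e-6,
        d_minor=376e-6,
        L_o=3.56e-3,
        h=1.1e-3,
        r_0=volume_to_radius(circulation.V_LV_init),
    )
    return VirtualTrabecula(geometry=geom)


# --- section parsers -------------------------------------------------------

_CIRC_KINDS = {
    "R_AV": "resistance", "R_SYS": "resistance", "R_TC": "resistance",
    "R_PV": "resistance", "R_PUL": "resistance", "R_MT": "resistance",
    "C_AO": "compliance", "C_VC": "compliance", "C_PA": "compliance",
    "C_PU": "compliance",
    "E_ESLV": "elastance", "E_ESRV": "elastance",
    "V_t": "volume", "V_s": "volume", "V_u": "volume",
    "V_LV_init": "volume", "V_RV_init": "volume",
}

_MUSCLE_KINDS = {
    "A": "area", "L_o": "length", "h": "length", "r_0": "length",
    "d_major": "length", "d_minor": "length",
    "sigma_max": "pressure", "passive_a": "pressure",
    "slack_rel": "dimensionless", "passive_b": "dimensionless",
    "heat_coeff": "dimensionless",
}


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")


def _parse_circulation(section: dict) -> CirculationParameters:
    _check_keys(section, set(_CIRC_KINDS) | {"unstressed_split"}, "circulation")
    kwargs = {}
    for key, raw in section.items():
        if key == "unstressed_split":
            kwargs[key] = tuple(parse_quantity(v, "volume") for v in raw)
        else:
            kwargs[key] = parse_quantity(raw, _CIRC_KINDS[key])
    try:
        return CirculationParameters(**kwargs)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc


def _parse_muscle(section: dict, circulation: CirculationParameters) -> VirtualTrabecula:
    _check_keys(section, set(_MUSCLE_KINDS) | {"activation"}, "muscle")
    vals = {
        k: parse_quantity(v, _MUSCLE_KINDS[k])
        for k, v in section.items()
        if k != "activation" and v is not None
    }

    act_sec = section.get("activation", {}) or {}
    _check_keys(act_sec, {"freq", "tau_rise", "tau_decay", "csv"}, "muscle.activation")
    act_kwargs = {}
    if "freq" in act_sec:
        act_kwargs["freq"] = parse_quantity(act_sec["freq"], "frequency")
    if "tau_rise" in act_sec:
        act_kwargs["tau_rise"] = parse_quantity(act_sec["tau_rise"], "time")
    if "tau_decay" in act_sec:
        act_kwargs["tau_decay"] = parse_quantity(act_sec["tau_decay"], "time")
    if "csv" in act_sec:
        import pandas as pd

        df = pd.read_csv(act_sec["csv"], comment="#")
        act_kwargs["samples"] = (
            tuple(float(x) for x in df.iloc[:, 0]),
            tuple(float(x) for x in df.iloc[:, 1]),
        )
    activation = TwitchActivation(**act_kwargs)

    base = default_muscle(circulation)
    d_major = vals.get("d_major", base.geometry.d_major)
    d_minor = vals.get("d_minor", base.geometry.d_minor)
    if "A" in vals:
        A = vals["A"]
    elif "d_major" in vals or "d_minor" in vals:
        A = ellipse_csa(d_major, d_minor)
    else:
        A = base.geometry.A
    geom = MuscleGeometry(
        A=A,
        L_o=vals.get("L_o", base.geometry.L_o),
        h=vals.get("h", base.geometry.h),
        r_0=vals.get("r_0", base.geometry.r_0),
        d_major=d_major,
        d_minor=d_minor,
    )
    return VirtualTrabecula(
        geometry=geom,
        activation=activation,
        sigma_max=vals.get("sigma_max", base.sigma_max),
        slack_rel=vals.get("slack_rel", base.slack_rel),
        passive_a=vals.get("passive_a", base.passive_a),
        passive_b=vals.get("passive_b", base.passive_b),
        heat_coeff=vals.get("heat_coeff", base.heat_coeff),
    )


def _parse_protocol(section: dict) -> ProtocolSettings:
    allowed = {
        "kind", "r_sys_grid", "edl", "isometric_length_rel",
        "restretch_duration", "restretch_threshold",
    }
    _check_keys(section, allowed, "protocol")
    kwargs = dict(section)
    if "r_sys_grid" in kwargs:
        kwargs["r_sys_grid"] = tuple(
            parse_quantity(v, "resistance") for v in kwargs["r_sys_grid"]
        )
    if "restretch_duration" in kwargs:
        kwargs["restretch_duration"] = parse_quantity(
            kwargs["restretch_duration"], "time"
        )
    return ProtocolSettings(**kwargs)


def _parse_integrator(section: dict) -> IntegratorSettings:
    _check_keys(section, {"dt", "n_cycles", "ss_tol"}, "integrator")
    kwargs = {}
    if "dt" in section:
        kwargs["dt"] = parse_quantity(section["dt"], "time")
    if "n_cycles" in section:
        kwargs["n_cycles"] = int(section["n_cycles"])
    if "ss_tol" in section:
        kwargs["ss_tol"] = parse_quantity(section["ss_tol"], "volume")
    return IntegratorSettings(**kwargs)


def _parse_fixtures(section: dict) -> FixtureSettings:
    allowed = {
        "n_twitches", "repeats", "noise_sd", "drift_rate",
        "sample_rate", "sensitivity", "dt",
    }
    _check_keys(section, allowed, "fixtures")
    kwargs = dict(section)
    if "noise_sd" in kwargs:
        kwargs["noise_sd"] = parse_quantity(kwargs["noise_sd"], "voltage")
    if "drift_rate" in kwargs:
        kwargs["drift_rate"] = float(kwargs["drift_rate"])
    if "sample_rate" in kwargs:
        kwargs["sample_rate"] = parse_quantity(kwargs["sample_rate"], "frequency")
    if "dt" in kwargs:
        kwargs["dt"] = parse_quantity(kwargs["dt"], "time")
    return FixtureSettings(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a configuration file; ``None`` or an empty file
    yields the full defaults."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        parsed = yaml.safe_load(text)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ConfigError("top level of config must be a mapping")
        raw = parsed

    _check_keys(
        raw,
        {"circulation", "muscle", "protocol", "integrator", "fixtures", "seed"},
        "config",
    )
    circulation = _parse_circulation(raw.get("circulation", {}) or {})
    muscle = _parse_muscle(raw.get("muscle", {}) or {}, circulation)
    cfg = RunConfig(
        circulation=circulation,
        muscle=muscle,
        protocol=_parse_protocol(raw.get("protocol", {}) or {}),
        integrator=_parse_integrator(raw.get("integrator", {}) or {}),
        fixtures=_parse_fixtures(raw.get("fixtures", {}) or {}),
        seed=int(raw.get("seed", 0)),
    )
    logger.info(
        "config resolved (digest %s): elastances read as %.3g/%.3g Pa·m^-3, "
        "compliance unit read as m^3·Pa^-1",
        cfg.digest(), circulation.E_ESLV, circulation.E_ESRV,
    )
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a resolved (SI-normalized) configuration back to YAML."""
    d = cfg.to_dict()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
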