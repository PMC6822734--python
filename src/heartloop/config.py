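"""YAML configuration round-tripping for circulation parameter sets.

The canonical file layout mirrors the model structure::

    units: {pressure: mmHg, volume: mL, length: cm, time: s, flow: mL/s}
    chambers:
      lv: {l, K, V0, E_es, A, B, T1, T2, T, axis_divisor}
      rv: {...}
      la: {l, K, V0, E_max, E_min, Ta, T, D}
      ra: {...}
    vessels:
      ao: {R, L, C}          # veins (vs, vp) omit L
      ...
    valves:
      mv: {R}
      ...
    solver:       # optional: max_step, rel_tol, abs_tol, n_cycles, ...
    calibration:  # optional: target_lv_edv, bracket

Loading is strict: a missing field or an unknown key fails with the YAML
path of the offender; physical invariants (positive R/C/E, T1 < T2 < T,
...) are enforced by the parameter classes themselves.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path
from typing import Any

import yaml

from .chambers import AtriumParams, VentricleParams
from .engine import SolverSettings
from .network import CirculationParams, ValveParams, VascularSegmentParams

__all__ = ["load_config", "load_config_full", "save_config", "ConfigError"]

UNITS_BLOCK = {"pressure": "mmHg", "volume": "mL", "length": "cm",
               "time": "s", "flow": "mL/s"}

# YAML uses plain "as"; the dataclass field is as_ ("as" is a Python keyword)
_VESSEL_KEYS = ("ao", "as", "vs", "po", "ap", "vp")
_VALVE_KEYS = ("mv", "av", "tv", "pv")


class ConfigError(ValueError):
    pass


def _build(cls, mapping: dict, where: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**mapping)
    except TypeError as exc:  # missing required field
        raise ConfigError(f"{where}: {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def _parse_params(doc: dict, where: str = "") -> CirculationParams:
    for section in ("chambers", "vessels", "valves"):
        if section not in doc:
            raise ConfigError(f"missing required section '{section}'")
    chambers, vessels, valves = doc["chambers"], doc["vessels"], doc["valves"]
    for name, got, want in (("chambers", chambers, ("lv", "rv", "la", "ra")),
                            ("vessels", vessels, _VESSEL_KEYS),
                            ("valves", valves, _VALVE_KEYS)):
        unknown = set(got) - set(want)
        missing = set(want) - set(got)
        if unknown:
            raise ConfigError(f"{name}: unknown key(s) {sorted(unknown)}")
        if missing:
            raise ConfigError(f"{name}: missing key(s) {sorted(missing)}")
    kwargs: dict[str, Any] = {
        "lv": _build(VentricleParams, chambers["lv"], "chambers.lv"),
        "rv": _build(VentricleParams, chambers["rv"], "chambers.rv"),
        "la": _build(AtriumParams, chambers["la"], "chambers.la"),
        "ra": _build(AtriumParams, chambers["ra"], "chambers.ra"),
    }
    for key in _VESSEL_KEYS:
        kwargs[key if key != "as" else "as_"] = _build(
            VascularSegmentParams, vessels[key], f"vessels.{key}")
    for key in _VALVE_KEYS:
        kwargs[key] = _build(ValveParams, valves[key], f"valves.{key}")
    try:
        return CirculationParams(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from None


def load_config_full(path) -> tuple[CirculationParams, SolverSettings | None, dict | None]:
    """Parse a config file into (CirculationParams, solver settings, calibration block)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known_top = {"units", "chambers", "vessels", "valves", "solver", "calibration"}
    unknown = set(doc) - known_top
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    params = _parse_params(doc)
    solver = None
    if "solver" in doc:
        solver = _build(SolverSettings, doc["solver"], "solver")
    calibration = doc.get("calibration")
    if calibration is not None:
        unknown = set(calibration) - {"target_lv_edv", "bracket", "total_stressed_volume"}
        if unknown:
            raise ConfigError(f"calibration: unknown key(s) {sorted(unknown)}")
    return params, solver, calibration


def load_config(path) -> CirculationParams:
    """Parse a config file, returning the circulation parameters only."""
    return load_config_full(path)[0]


def save_config(params: CirculationParams, path,
                solver: SolverSettings | None = None,
                calibration: dict | None = None) -> None:
    """Write a config file that load_config restores field-for-field."""
    doc: dict[str, Any] = {"units": dict(UNITS_BLOCK)}
    doc["chambers"] = {k: asdict(getattr(params, k)) for k in ("lv", "rv", "la", "ra")}
    vessels = {}
    for key in _VESSEL_KEYS:
        seg = asdict(getattr(params, key if key != "as" else "as_"))
        if seg["L"] == 0.0:
            del seg["L"]  # venous segments carry no inertance
        vessels[key] = seg
    doc["vessels"] = vessels
    doc["valves"] = {k: asdict(getattr(params, k)) for k in _VALVE_KEYS}
    if solver is not None:
        doc["solver"] = asdict(solver)
    if calibration is not None:
        doc["calibration"] = dict(calibration)
    with open(path, "w") as fh:
        fh.write("# heartloop circulation config; units: mmHg, mL, cm, s "
                 "(R mmHg·s/mL, L mmHg·s²/mL, C mL/mmHg, elastance mmHg/mL)\n")
        yaml.safe_dump(doc, fh, sort_keys=False)
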