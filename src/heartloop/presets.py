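"""Named scenario presets: adult/child, healthy/DCM.

All numbers are the published model constants for a healthy adult, a
healthy child (body surface area 1 m², ages 8-12) and the corresponding
dilated-cardiomyopathy (DCM) variants.  DCM touches exactly five
parameters — LV scaling coefficient K, LV zero-pressure volume V0, LV
end-systolic elastance E_es, LV passive amplitude A, and the systemic
arteriolar resistance — leaving the rest of the loop untouched.

Activation timing is stored as fractions of the cycle length (T1 = 0.33 T,
T2 = 0.45 T, Ta = 0.8 T), so overriding the heart rate rescales the phase
structure consistently; the atrial delay D is an absolute time.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, is_dataclass, replace
from typing import Any

from .chambers import AtriumParams, VentricleParams
from .network import CirculationParams, ValveParams, VascularSegmentParams

__all__ = ["ScenarioPreset", "get_preset", "list_presets", "diff_presets",
           "PRESET_NAMES", "DCM_MODIFIED_PARAMS"]

PRESET_NAMES = ("adult-healthy", "adult-dcm", "child-healthy", "child-dcm")

# the five parameters a DCM scenario overrides, as (section, field) paths
DCM_MODIFIED_PARAMS = frozenset({
    ("lv", "K"), ("lv", "V0"), ("lv", "E_es"), ("lv", "A"), ("as_", "R"),
})

T1_FRAC, T2_FRAC, TA_FRAC = 0.33, 0.45, 0.8


def _ventricle(l, K, V0, E_es, A, T, divisor, B=0.02):
    return VentricleParams(l=l, K=K, V0=V0, E_es=E_es, A=A, B=B,
                           T1=T1_FRAC * T, T2=T2_FRAC * T, T=T,
                           axis_divisor=divisor)


def _atrium(l, K, V0, E_max, E_min, T, D):
    return AtriumParams(l=l, K=K, V0=V0, E_max=E_max, E_min=E_min,
                        Ta=TA_FRAC * T, T=T, D=D)


def _adult_circulation(dcm: bool) -> CirculationParams:
    T = 0.8
    return CirculationParams(
        lv=_ventricle(l=8, K=0.95 if dcm else 1.15, V0=25 if dcm else 15,
                      E_es=0.9 if dcm else 2.5, A=0.65 if dcm else 1.0,
                      T=T, divisor=2),
        rv=_ventricle(l=8, K=1.75, V0=40, E_es=1.0, A=1.0, T=T, divisor=4),
        la=_atrium(l=5.5, K=1.20, V0=5, E_max=0.3, E_min=0.2, T=T, D=0.04),
        ra=_atrium(l=5.5, K=1.20, V0=5, E_max=0.3, E_min=0.2, T=T, D=0.04),
        ao=VascularSegmentParams(R=0.05, L=1e-5, C=0.2),
        as_=VascularSegmentParams(R=1.6 if dcm else 0.95, L=1e-5, C=1.7),
        vs=VascularSegmentParams(R=0.05, C=30.0),
        po=VascularSegmentParams(R=0.01, L=1e-5, C=5.0),
        ap=VascularSegmentParams(R=0.15, L=1e-5, C=0.2),
        vp=VascularSegmentParams(R=0.05, C=30.0),
        mv=ValveParams(R=0.002), av=ValveParams(R=0.002),
        tv=ValveParams(R=0.001), pv=ValveParams(R=0.001),
    )


def _child_circulation(dcm: bool) -> CirculationParams:
    T = 0.75
    return CirculationParams(
        lv=_ventricle(l=7, K=1.40 if dcm else 1.50, V0=17 if dcm else 10,
                      E_es=1.3 if dcm else 3.5, A=0.85 if dcm else 1.0,
                      T=T, divisor=2),
        rv=_ventricle(l=7, K=3.25, V0=25, E_es=1.4, A=1.0, T=T, divisor=4),
        la=_atrium(l=4.5, K=2.50, V0=3, E_max=0.4, E_min=0.2, T=T, D=0.0375),
        ra=_atrium(l=4.5, K=2.50, V0=3, E_max=0.4, E_min=0.2, T=T, D=0.0375),
        ao=VascularSegmentParams(R=0.05, L=1e-5, C=0.13),
        as_=VascularSegmentParams(R=1.4 if dcm else 0.95, L=1e-5, C=1.13),
        vs=VascularSegmentParams(R=0.05, C=19.35),
        po=VascularSegmentParams(R=0.01, L=1e-5, C=3.33),
        ap=VascularSegmentParams(R=0.15, L=1e-5, C=0.13),
        vp=VascularSegmentParams(R=0.05, C=19.35),
        mv=ValveParams(R=0.002), av=ValveParams(R=0.002),
        tv=ValveParams(R=0.001), pv=ValveParams(R=0.001),
    )


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully-populated circulation model plus its calibration anchor.

    ``target_lv_edv`` is the LV end-diastolic volume (mL) the healthy model
    of each age group is calibrated to; DCM scenarios inherit the
    calibrated total stressed volume of their healthy counterpart instead
    of recalibrating (the closed loop conserves volume, so disease changes
    only redistribute it).  ``calibration_bracket`` bounds the stressed
    volume search.
    """

    name: str
    params: CirculationParams
    target_lv_edv: float
    calibration_bracket: tuple[float, float]
    healthy_counterpart: str


_PRESETS = {
    "adult-healthy": lambda: ScenarioPreset(
        name="adult-healthy", params=_adult_circulation(False),
        target_lv_edv=125.0, calibration_bracket=(600.0, 2600.0),
        healthy_counterpart="adult-healthy"),
    "adult-dcm": lambda: ScenarioPreset(
        name="adult-dcm", params=_adult_circulation(True),
        target_lv_edv=125.0, calibration_bracket=(600.0, 2600.0),
        healthy_counterpart="adult-healthy"),
    "child-healthy": lambda: ScenarioPreset(
        name="child-healthy", params=_child_circulation(False),
        target_lv_edv=92.0, calibration_bracket=(400.0, 1800.0),
        healthy_counterpart="child-healthy"),
    "child-dcm": lambda: ScenarioPreset(
        name="child-dcm", params=_child_circulation(True),
        target_lv_edv=92.0, calibration_bracket=(400.0, 1800.0),
        healthy_counterpart="child-healthy"),
}


def list_presets() -> tuple[str, ...]:
    return PRESET_NAMES


def get_preset(name: str) -> ScenarioPreset:
    """Return a validated scenario preset by name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


def _flatten(params: CirculationParams) -> dict[tuple[str, str], Any]:
    out: dict[tuple[str, str], Any] = {}
    for sec in fields(params):
        sub = getattr(params, sec.name)
        for f in fields(sub):
            out[(sec.name, f.name)] = getattr(sub, f.name)
    return out


def diff_presets(a: ScenarioPreset | CirculationParams,
                 b: ScenarioPreset | CirculationParams):
    """Exhaustive structural diff: list of ((section, field), value_a, value_b)."""
    pa = a.params if isinstance(a, ScenarioPreset) else a
    pb = b.params if isinstance(b, ScenarioPreset) else b
    fa, fb = _flatten(pa), _flatten(pb)
    return [(k, fa[k], fb[k]) for k in fa if fa[k] != fb[k]]
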