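"""Clinical indices: reduce a converged cycle to echo-style diagnostics.

End-diastole (ED) and end-systole (ES) are defined by the ventricular
volume extrema over the final cycle, which is robust to valve-diode
chatter.  Diameters are twice the mid-cavity radius, except the right
ventricle, whose basal diameter is reported as the RV radius itself (the
trimmed-ellipsoid RV is roughly half a cavity wide).  The LV sphericity
index divides the long-axis length by the mid-cavity diameter of the
ellipsoid at half the long axis, D_mid = sqrt(3) * r.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, fields
from math import sqrt

import numpy as np
import pandas as pd

from .engine import SimulationResult

__all__ = [
    "IndicesReport",
    "cycle_landmarks",
    "ejection_metrics",
    "fractional_shortening",
    "sphericity_index",
    "chamber_diameters",
    "mean_pressures",
    "compute_indices",
]

INDEX_UNITS = {
    "LVEDV": "mL", "LVESV": "mL", "RVEDV": "mL", "RVESV": "mL",
    "LAV_max": "mL", "LAV_min": "mL", "RAV_max": "mL", "RAV_min": "mL",
    "LVEDD": "cm", "LVESD": "cm", "RVEDD": "cm", "RVESD": "cm",
    "LAD_max": "cm", "LAD_min": "cm", "RAD_max": "cm", "RAD_min": "cm",
    "LVSV": "mL", "CO": "L/min", "LVEF": "%", "RVEF": "%", "fs": "%",
    "Dsi": "-", "Ssi": "-", "MAP": "mmHg", "MPAP": "mmHg",
}


@dataclass(frozen=True)
class IndicesReport:
    """Diagnostic indicators of one scenario at periodic steady state."""

    LVEDV: float
    LVESV: float
    RVEDV: float
    RVESV: float
    LAV_max: float
    LAV_min: float
    RAV_max: float
    RAV_min: float
    LVEDD: float
    LVESD: float
    RVEDD: float
    RVESD: float
    LAD_max: float
    LAD_min: float
    RAD_max: float
    RAD_min: float
    LVSV: float
    CO: float
    LVEF: float
    RVEF: float
    fs: float
    Dsi: float
    Ssi: float
    MAP: float
    MPAP: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.LVESV < self.LVEDV):
            raise ValueError("LV volumes must satisfy 0 <= ESV < EDV")
        if not (0.0 <= self.LVEF <= 100.0 and 0.0 <= self.RVEF <= 100.0):
            raise ValueError("ejection fractions must lie in [0, 100]%")
        fs_check = 100.0 * (self.LVEDD - self.LVESD) / self.LVEDD
        if abs(fs_check - self.fs) > 1e-9 * max(1.0, abs(self.fs)):
            raise ValueError("fs inconsistent with LVEDD/LVESD")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        payload = {k: v for k, v in self.to_dict().items()}
        payload["units"] = INDEX_UNITS
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_row(self, name: str) -> pd.DataFrame:
        """One comparison-table row for a scenarios CSV."""
        d = {"scenario": name}
        d.update({k: v for k, v in self.to_dict().items() if k != "converged"})
        return pd.DataFrame([d]).set_index("scenario")


def cycle_landmarks(result: SimulationResult) -> dict[str, float]:
    """Times (s, within the cycle) of the volume extrema of each chamber."""
    if not result.converged:
        warnings.warn("landmarks computed on a non-converged cycle", RuntimeWarning)
    t = result.t
    out = {}
    for key, name in (("lv", "V_lv"), ("rv", "V_rv")):
        v = result.state(name)
        out[f"t_ED_{key}"] = float(t[int(np.argmax(v))])
        out[f"t_ES_{key}"] = float(t[int(np.argmin(v))])
    for key, name in (("la", "V_la"), ("ra", "V_ra")):
        v = result.state(name)
        out[f"t_max_{key}"] = float(t[int(np.argmax(v))])
        out[f"t_min_{key}"] = float(t[int(np.argmin(v))])
    return out


def ejection_metrics(result: SimulationResult) -> dict[str, float]:
    """Stroke volume (mL), cardiac output (L/min) and ejection fractions (%)."""
    out = {}
    for key, name in (("lv", "V_lv"), ("rv", "V_rv")):
        v = result.state(name)
        edv, esv = float(v.max()), float(v.min())
        if edv <= 0:
            raise ValueError(f"{key} end-diastolic volume is zero")
        out[f"{key}_EDV"], out[f"{key}_ESV"] = edv, esv
        out[f"{key}_SV"] = edv - esv
        out[f"{key}_EF"] = 100.0 * (edv - esv) / edv
    out["CO"] = out["lv_SV"] * (60.0 / result.T) / 1000.0
    return out


def fractional_shortening(EDD: float, ESD: float) -> float:
    """Percent shortening of the LV minor-axis diameter, 100*(EDD-ESD)/EDD."""
    if EDD <= 0:
        raise ValueError("EDD must be positive")
    return 100.0 * (EDD - ESD) / EDD


def sphericity_index(l: float, r_at_landmark: float) -> float:
    """Long axis over mid-cavity diameter; lower = more globular ventricle.

    For an ellipsoid of mid-cavity radius r, the cross-section diameter at
    half the long axis is sqrt(3)*r.
    """
    if r_at_landmark <= 0:
        raise ValueError("radius must be positive")
    return l / (sqrt(3.0) * r_at_landmark)


def chamber_diameters(result: SimulationResult) -> dict[str, float]:
    """ED/ES and max/min diameters (cm); RV uses the basal-diameter convention."""
    d = {}
    d_lv = result.diameters["d_lv"]
    d["LVEDD"], d["LVESD"] = float(d_lv.max()), float(d_lv.min())
    d_rv = result.diameters["d_rv"]  # = r_rv
    d["RVEDD"], d["RVESD"] = float(d_rv.max()), float(d_rv.min())
    for key, col in (("LAD", "d_la"), ("RAD", "d_ra")):
        dd = result.diameters[col]
        d[f"{key}_max"], d[f"{key}_min"] = float(dd.max()), float(dd.min())
    return d


def mean_pressures(result: SimulationResult) -> dict[str, float]:
    """Trapezoidal cycle averages of aortic and pulmonary arterial pressure."""
    t = result.t
    T = t[-1] - t[0]
    return {
        "MAP": float(np.trapezoid(result.pressures["p_ao"], t) / T),
        "MPAP": float(np.trapezoid(result.pressures["p_po"], t) / T),
    }


def compute_indices(result: SimulationResult) -> IndicesReport:
    """Assemble the full diagnostic report for one converged cycle."""
    ej = ejection_metrics(result)
    dia = chamber_diameters(result)
    mp = mean_pressures(result)
    r_lv = result.radii["r_lv"]
    v_lv = result.state("V_lv")
    r_ed = float(r_lv[int(np.argmax(v_lv))])
    r_es = float(r_lv[int(np.argmin(v_lv))])
    l_lv = result.params.lv.l
    return IndicesReport(
        LVEDV=ej["lv_EDV"], LVESV=ej["lv_ESV"],
        RVEDV=ej["rv_EDV"], RVESV=ej["rv_ESV"],
        LAV_max=float(result.state("V_la").max()),
        LAV_min=float(result.state("V_la").min()),
        RAV_max=float(result.state("V_ra").max()),
        RAV_min=float(result.state("V_ra").min()),
        **dia,
        LVSV=ej["lv_SV"], CO=ej["CO"],
        LVEF=ej["lv_EF"], RVEF=ej["rv_EF"],
        fs=fractional_shortening(dia["LVEDD"], dia["LVESD"]),
        Dsi=sphericity_index(l_lv, r_ed),
        Ssi=sphericity_index(l_lv, r_es),
        **mp,
        converged=result.converged,
    )
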