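"""Closed-loop circulation network: 14-state ODE right-hand side.

Topology (electrical analogy, one shunt compliance per segment inlet node,
series R + L carrying flow to the next node):

    LA --MV--> LV --AV--> [ao] --RL--> [as] --RL--> [vs] --R--> RA
    RA --TV--> RV --PV--> [po] --RL--> [ap] --RL--> [vp] --R--> LA

The four heart valves are ideal diodes (one-way, resistive when open);
venous return paths (vs -> RA, vp -> LA) are plain bidirectional
resistances.  State vector (14 components, fixed order):

    V_lv, V_rv, V_la, V_ra              chamber volumes, mL
    p_ao, p_as, p_vs, p_po, p_ap, p_vp  compliance node pressures, mmHg
    Q_ao, Q_as, Q_po, Q_ap              inertance flows, mL/s

Valve flows are algebraic outputs, not state.  Units are mmHg / mL / s
everywhere; no conversion happens at module boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .chambers import (
    AtriumParams,
    VentricleParams,
    atrial_elastance,
    radius_from_volume,
    ventricle_pressure,
)

__all__ = [
    "VascularSegmentParams",
    "ValveParams",
    "CirculationParams",
    "ModelState",
    "STATE_NAMES",
    "valve_flow",
    "state_derivative",
    "chamber_pressures",
    "total_stressed_volume",
]

STATE_NAMES = (
    "V_lv", "V_rv", "V_la", "V_ra",
    "p_ao", "p_as", "p_vs", "p_po", "p_ap", "p_vp",
    "Q_ao", "Q_as", "Q_po", "Q_ap",
)


@dataclass(frozen=True)
class VascularSegmentParams:
    """One lumped vessel segment: resistance R (mmHg·s/mL), inertance L
    (mmHg·s²/mL, 0 for purely resistive-capacitive venous segments) and
    compliance C (mL/mmHg)."""

    R: float
    C: float
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"segment resistance must be positive, got R={self.R}")
        if self.C <= 0:
            raise ValueError(f"segment compliance must be positive, got C={self.C}")
        if self.L < 0:
            raise ValueError(f"segment inertance must be >= 0, got L={self.L}")


@dataclass(frozen=True)
class ValveParams:
    """Ideal-diode heart valve: forward resistance R in mmHg·s/mL."""

    R: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"valve resistance must be positive, got R={self.R}")


@dataclass(frozen=True)
class CirculationParams:
    """Full parameter set of the closed loop: four chambers, six vascular
    segments (ao aorta, as_ systemic arterioles, vs systemic veins, po
    pulmonary arteries, ap pulmonary arterioles, vp pulmonary veins) and
    four valves (mv, av, tv, pv)."""

    lv: VentricleParams
    rv: VentricleParams
    la: AtriumParams
    ra: AtriumParams
    ao: VascularSegmentParams
    as_: VascularSegmentParams
    vs: VascularSegmentParams
    po: VascularSegmentParams
    ap: VascularSegmentParams
    vp: VascularSegmentParams
    mv: ValveParams
    av: ValveParams
    tv: ValveParams
    pv: ValveParams

    def __post_init__(self) -> None:
        periods = {self.lv.T, self.rv.T, self.la.T, self.ra.T}
        if len(periods) != 1:
            raise ValueError(f"all chamber cycle durations must agree, got {sorted(periods)}")

    @property
    def T(self) -> float:
        """Cardiac cycle duration, s."""
        return self.lv.T


@dataclass
class ModelState:
    """Named view of the 14-component dynamic state."""

    V_lv: float
    V_rv: float
    V_la: float
    V_ra: float
    p_ao: float
    p_as: float
    p_vs: float
    p_po: float
    p_ap: float
    p_vp: float
    Q_ao: float
    Q_as: float
    Q_po: float
    Q_ap: float

    def __post_init__(self) -> None:
        for name in ("V_lv", "V_rv", "V_la", "V_ra"):
            if getattr(self, name) < 0:
                raise ValueError(f"chamber volume {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (14,):
            raise ValueError(f"state vector must have 14 components, got shape {y.shape}")
        return cls(*y)


def valve_flow(p_up: float, p_down: float, v: ValveParams) -> float:
    """Ideal-diode flow: forward Ohmic conduction, zero reverse flow (mL/s)."""
    dp = p_up - p_down
    return dp / v.R if dp > 0.0 else 0.0


def chamber_pressures(t, V_lv, V_rv, V_la, V_ra, p: CirculationParams):
    """Pressures of the four chambers at time(s) t from their volumes, mmHg."""
    p_lv = ventricle_pressure(radius_from_volume(np.maximum(V_lv, 0.0), p.lv), t, p.lv)
    p_rv = ventricle_pressure(radius_from_volume(np.maximum(V_rv, 0.0), p.rv), t, p.rv)
    p_la = atrial_elastance(t, p.la) * (np.maximum(V_la, 0.0) - p.la.V0)
    p_ra = atrial_elastance(t, p.ra) * (np.maximum(V_ra, 0.0) - p.ra.V0)
    return p_lv, p_rv, p_la, p_ra


def state_derivative(t: float, y: np.ndarray, p: CirculationParams) -> np.ndarray:
    """Time derivative of the 14-component state vector.

    Chamber pressures are evaluated from volume through the ellipsoidal
    radius; valve flows are diode-gated; each compliance node obeys
    C dp/dt = inflow - outflow and each inertance L dQ/dt = dp - R Q.
    """
    (V_lv, V_rv, V_la, V_ra,
     p_ao, p_as, p_vs, p_po, p_ap, p_vp,
     Q_ao, Q_as, Q_po, Q_ap) = y

    if V_lv < 0 or V_rv < 0 or V_la < 0 or V_ra < 0:
        warnings.warn("negative chamber volume encountered; radius clamped at 0", RuntimeWarning)

    p_lv, p_rv, p_la, p_ra = chamber_pressures(t, V_lv, V_rv, V_la, V_ra, p)

    Q_mv = valve_flow(p_la, p_lv, p.mv)
    Q_av = valve_flow(p_lv, p_ao, p.av)
    Q_tv = valve_flow(p_ra, p_rv, p.tv)
    Q_pv = valve_flow(p_rv, p_po, p.pv)

    # venous returns: bidirectional resistive paths
    Q_vs = (p_vs - p_ra) / p.vs.R
    Q_vp = (p_vp - p_la) / p.vp.R

    return np.array([
        Q_mv - Q_av,                                   # dV_lv/dt
        Q_tv - Q_pv,                                   # dV_rv/dt
        Q_vp - Q_mv,                                   # dV_la/dt
        Q_vs - Q_tv,                                   # dV_ra/dt
        (Q_av - Q_ao) / p.ao.C,                        # dp_ao/dt
        (Q_ao - Q_as) / p.as_.C,                       # dp_as/dt
        (Q_as - Q_vs) / p.vs.C,                        # dp_vs/dt
        (Q_pv - Q_po) / p.po.C,                        # dp_po/dt
        (Q_po - Q_ap) / p.ap.C,                        # dp_ap/dt
        (Q_ap - Q_vp) / p.vp.C,                        # dp_vp/dt
        (p_ao - p_as - p.ao.R * Q_ao) / p.ao.L,        # dQ_ao/dt
        (p_as - p_vs - p.as_.R * Q_as) / p.as_.L,      # dQ_as/dt
        (p_po - p_ap - p.po.R * Q_po) / p.po.L,        # dQ_po/dt
        (p_ap - p_vp - p.ap.R * Q_ap) / p.ap.L,        # dQ_ap/dt
    ])


def algebraic_flows(t, y, p: CirculationParams):
    """Valve and venous flows (mL/s) as functions of state; vectorized over time."""
    V_lv, V_rv, V_la, V_ra = y[0], y[1], y[2], y[3]
    p_ao, p_vs, p_po, p_vp = y[4], y[6], y[7], y[9]
    p_lv, p_rv, p_la, p_ra = chamber_pressures(t, V_lv, V_rv, V_la, V_ra, p)
    Q_mv = np.maximum(p_la - p_lv, 0.0) / p.mv.R
    Q_av = np.maximum(p_lv - p_ao, 0.0) / p.av.R
    Q_tv = np.maximum(p_ra - p_rv, 0.0) / p.tv.R
    Q_pv = np.maximum(p_rv - p_po, 0.0) / p.pv.R
    Q_vs = (p_vs - p_ra) / p.vs.R
    Q_vp = (p_vp - p_la) / p.vp.R
    return Q_mv, Q_av, Q_tv, Q_pv, Q_vs, Q_vp


def total_stressed_volume(y: np.ndarray | ModelState, p: CirculationParams) -> float:
    """Total blood volume held in chambers plus compliances (mL); conserved
    along any trajectory of the closed loop."""
    if isinstance(y, ModelState):
        y = y.to_array()
    y = np.asarray(y, dtype=float)
    chambers = y[0] + y[1] + y[2] + y[3]
    caps = (p.ao.C * y[4] + p.as_.C * y[5] + p.vs.C * y[6]
            + p.po.C * y[7] + p.ap.C * y[8] + p.vp.C * y[9])
    return float(chambers + caps)
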