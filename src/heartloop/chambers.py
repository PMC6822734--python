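"""Chamber mechanics: ellipsoidal geometry and time-varying elastance pressure laws.

Each heart chamber is a truncated ellipsoid of revolution with constant
long-axis length ``l`` and a dimensionless scaling coefficient ``K`` that
absorbs long-axis contraction and shape irregularity.  Chamber volume and
mid-cavity radius are then algebraically linked,

    V = (4/3) * pi * K * r**2 * (l / axis_divisor),

with ``axis_divisor = 2`` for the left ventricle and both atria (half
ellipsoid) and ``axis_divisor = 4`` for the right ventricle, whose crescentic
cavity is modelled as an ellipsoid trimmed at both the long and the basal
axis.  Pressure follows a time-varying elastance law: ventricles combine an
activation-gated active term ``E_es * (V - V0) * f(t)`` with an exponential
passive term ``A * exp(B*V) - 1``; atria use a sinusoidal elastance swinging
between ``E_min`` and ``E_max`` with a delayed activation burst late in the
cycle (atrial kick).

All functions are pure, accept scalar or ndarray ``t`` / ``r`` arguments, and
work in mmHg / mL / cm / s throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "VentricleParams",
    "AtriumParams",
    "ChamberKinematics",
    "volume_from_radius",
    "radius_from_volume",
    "ventricular_activation",
    "atrial_activation",
    "atrial_elastance",
    "ventricle_active_pressure",
    "ventricle_passive_pressure",
    "ventricle_pressure",
    "atrium_pressure",
]


@dataclass(frozen=True)
class VentricleParams:
    """Geometric and elastance parameters of one ventricle.

    Attributes
    ----------
    l : float
        Long-axis (base-to-apex) length, cm.  Constant over the cycle.
    K : float
        Dimensionless scaling coefficient linking radius and volume.
    V0 : float
        Zero-pressure volume, mL (volume at which active pressure vanishes).
    E_es : float
        End-systolic elastance, mmHg/mL.
    A : float
        Passive pressure amplitude, mmHg.
    B : float
        Passive pressure exponent, 1/mL.
    T1 : float
        End of systole within the cycle, s.
    T2 : float
        End of active relaxation, s.
    T : float
        Cardiac cycle duration, s.
    axis_divisor : int
        2 for a half ellipsoid (LV), 4 for the trimmed RV ellipsoid.
    subtract_A : bool
        If True the passive law is read as ``A*(exp(B*V) - 1)`` instead of
        the default ``A*exp(B*V) - 1``; the two differ by the constant
        ``A - 1``, which is nonzero only when A != 1.
    """

    l: float
    K: float
    V0: float
    E_es: float
    A: float
    B: float
    T1: float
    T2: float
    T: float
    axis_divisor: int = 2
    subtract_A: bool = False

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"long-axis length must be positive, got l={self.l}")
        if self.K <= 0:
            raise ValueError(f"scaling coefficient must be positive, got K={self.K}")
        if self.V0 < 0:
            raise ValueError(f"zero-pressure volume must be >= 0, got V0={self.V0}")
        if self.E_es <= 0:
            raise ValueError(f"end-systolic elastance must be positive, got E_es={self.E_es}")
        if self.B <= 0:
            raise ValueError(f"passive exponent must be positive, got B={self.B}")
        if not (0 < self.T1 < self.T2 < self.T):
            raise ValueError(
                f"timing must satisfy 0 < T1 < T2 < T, got T1={self.T1}, T2={self.T2}, T={self.T}"
            )
        if self.axis_divisor not in (2, 4):
            raise ValueError(f"axis_divisor must be 2 or 4, got {self.axis_divisor}")

    @property
    def r0(self) -> float:
        """Radius at the zero-pressure volume, cm."""
        return radius_from_volume(self.V0, self)


@dataclass(frozen=True)
class AtriumParams:
    """Geometric and elastance parameters of one atrium.

    The atrium is a half ellipsoid (axis_divisor fixed at 2) whose elastance
    swings between ``E_min`` and ``E_max`` driven by an activation waveform
    that starts at ``Ta`` and is applied with delay ``D`` (wrapping across
    the cycle boundary, so the atrial kick lands in late diastole).
    """

    l: float
    K: float
    V0: float
    E_max: float
    E_min: float
    Ta: float
    T: float
    D: float
    axis_divisor: int = field(default=2)

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"length must be positive, got l={self.l}")
        if self.K <= 0:
            raise ValueError(f"scaling coefficient must be positive, got K={self.K}")
        if self.V0 < 0:
            raise ValueError(f"zero-pressure volume must be >= 0, got V0={self.V0}")
        if not (self.E_max >= self.E_min > 0):
            raise ValueError(
                f"elastances must satisfy E_max >= E_min > 0, got E_max={self.E_max}, E_min={self.E_min}"
            )
        if not (0 < self.Ta < self.T):
            raise ValueError(f"activation onset must satisfy 0 < Ta < T, got Ta={self.Ta}, T={self.T}")
        if not (0 <= self.D < self.T):
            raise ValueError(f"delay must satisfy 0 <= D < T, got D={self.D}")
        if self.axis_divisor != 2:
            raise ValueError("atrial axis_divisor is fixed at 2")

    @property
    def r0(self) -> float:
        return radius_from_volume(self.V0, self)


@dataclass(frozen=True)
class ChamberKinematics:
    """Volume, radius and mid-cavity diameter of one chamber at one instant."""

    V: float
    r: float

    def __post_init__(self) -> None:
        if self.V < 0 or self.r < 0:
            raise ValueError("volume and radius must be non-negative")

    @property
    def d(self) -> float:
        return 2.0 * self.r


def _geometry_factor(p: VentricleParams | AtriumParams) -> float:
    """(4/3)*pi*K*(l/axis_divisor): the V = factor * r**2 proportionality."""
    return (4.0 / 3.0) * np.pi * p.K * p.l / p.axis_divisor


def volume_from_radius(r: ArrayLike, p: VentricleParams | AtriumParams) -> ArrayLike:
    """Chamber volume (mL) from mid-cavity radius (cm)."""
    if np.any(np.asarray(r) < 0):
        raise ValueError("radius must be non-negative")
    return _geometry_factor(p) * np.square(r)


def radius_from_volume(V: ArrayLike, p: VentricleParams | AtriumParams) -> ArrayLike:
    """Mid-cavity radius (cm) from chamber volume (mL); exact inverse of volume_from_radius."""
    if np.any(np.asarray(V) < 0):
        raise ValueError("volume must be non-negative")
    return np.sqrt(np.asarray(V, dtype=float) / _geometry_factor(p))


def ventricular_activation(t: ArrayLike, p: VentricleParams) -> ArrayLike:
    """Ventricular activation waveform in [0, 1].

    Raised-cosine upstroke on [0, T1), raised-cosine relaxation on [T1, T2),
    zero on [T2, T).  ``t`` is reduced modulo the cycle length.
    """
    tc = np.mod(t, p.T)
    up = (1.0 - np.cos(np.pi * tc / p.T1)) / 2.0
    down = (1.0 + np.cos(np.pi * (tc - p.T1) / (p.T2 - p.T1))) / 2.0
    return np.where(tc < p.T1, up, np.where(tc < p.T2, down, 0.0))


def atrial_activation(t: ArrayLike, p: AtriumParams) -> ArrayLike:
    """Atrial activation waveform in [0, 2]: a single cosine bump on [Ta, T)."""
    tc = np.mod(t, p.T)
    bump = 1.0 - np.cos(2.0 * np.pi * (tc - p.Ta) / (p.T - p.Ta))
    return np.where(tc < p.Ta, 0.0, bump)


def atrial_elastance(t: ArrayLike, p: AtriumParams) -> ArrayLike:
    """Time-varying atrial elastance, mmHg/mL.

    E(t) = E_min + 0.5*(E_max - E_min)*f((t - D) mod T); the activation
    delay D wraps across the cycle boundary.
    """
    return p.E_min + 0.5 * (p.E_max - p.E_min) * atrial_activation(np.mod(np.asarray(t) - p.D, p.T), p)


def ventricle_active_pressure(r: ArrayLike, t: ArrayLike, p: VentricleParams) -> ArrayLike:
    """Active ventricular pressure E_es*(V(r) - V0)*f(t), mmHg.

    Negative values are allowed when V < V0 (suction below the
    zero-pressure volume).
    """
    return p.E_es * (volume_from_radius(r, p) - p.V0) * ventricular_activation(t, p)


def ventricle_passive_pressure(r: ArrayLike, p: VentricleParams) -> ArrayLike:
    """Passive (diastolic) ventricular pressure, mmHg.

    Default reading is ``A*exp(B*V) - 1``; with ``subtract_A`` the constant
    offset moves inside: ``A*(exp(B*V) - 1)``.
    """
    expBV = np.exp(p.B * volume_from_radius(r, p))
    if p.subtract_A:
        return p.A * (expBV - 1.0)
    return p.A * expBV - 1.0


def ventricle_pressure(r: ArrayLike, t: ArrayLike, p: VentricleParams) -> ArrayLike:
    """Total ventricular pressure: active plus passive component, mmHg."""
    return ventricle_active_pressure(r, t, p) + ventricle_passive_pressure(r, p)


def atrium_pressure(r: ArrayLike, t: ArrayLike, p: AtriumParams) -> ArrayLike:
    """Atrial pressure E(t)*(V(r) - V0), mmHg."""
    return atrial_elastance(t, p) * (volume_from_radius(r, p) - p.V0)
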