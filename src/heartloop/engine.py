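"""Simulation engine: stiff integration to periodic steady state and
stressed-volume calibration.

The 14-state closed loop is integrated cycle by cycle with a stiff
multistep solver (BDF, the SciPy analogue of ode15s) at a maximum step of
1 ms and relative tolerance 1e-3.  Convergence to periodic steady state is
declared when the cycle means of LV volume and aortic pressure both change
by less than ``steady_tol`` (relative) between consecutive cycles.

The loop conserves total stressed volume exactly, and the model's only
free quantity is how much blood it holds: ``calibrate_total_volume``
adjusts the total until the steady-state LV end-diastolic volume hits a
stated target, after which every other output is a genuine prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chambers import radius_from_volume
from .network import (
    STATE_NAMES,
    CirculationParams,
    ModelState,
    algebraic_flows,
    chamber_pressures,
    state_derivative,
    total_stressed_volume,
)

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "run_to_steady_state",
    "default_initial_state",
    "calibrate_total_volume",
    "CalibrationError",
]

FLOW_NAMES = ("Q_mv", "Q_av", "Q_tv", "Q_pv", "Q_vs", "Q_vp")


@dataclass(frozen=True)
class SolverSettings:
    """Integration and convergence settings.

    max_step 1e-3 s and rel_tol 1e-3 match the stiff-solver configuration
    the model was designed around; abs_tol is in model units (mL, mmHg,
    mL/s).  ``output_dt`` sets the sampling grid of the returned cycle.
    """

    max_step: float = 1e-3
    rel_tol: float = 1e-3
    abs_tol: float = 1e-6
    n_cycles: int = 60
    steady_tol: float = 1e-3
    output_dt: float = 1e-3
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be at least 2")


@dataclass
class SimulationResult:
    """One sampled cycle at periodic steady state plus derived signals.

    ``t`` spans exactly one period [0, T] inclusive; ``states`` is the
    (14, len(t)) trajectory in STATE_NAMES order.  Derived chamber
    pressures, valve/venous flows, radii and diameters are computed on the
    same grid.  ``d_rv`` follows the right-ventricular basal-diameter
    convention (equal to the RV radius, not twice it).
    """

    t: np.ndarray
    states: np.ndarray
    params: CirculationParams
    converged: bool
    n_cycles_run: int
    cycle_history: pd.DataFrame  # per-cycle mean V_lv and mean p_ao
    pressures: dict[str, np.ndarray] = field(default_factory=dict)
    flows: dict[str, np.ndarray] = field(default_factory=dict)
    radii: dict[str, np.ndarray] = field(default_factory=dict)
    diameters: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        p = self.params
        y = self.states
        t = self.t
        p_lv, p_rv, p_la, p_ra = chamber_pressures(t, y[0], y[1], y[2], y[3], p)
        self.pressures = {
            "p_lv": p_lv, "p_rv": p_rv, "p_la": p_la, "p_ra": p_ra,
            "p_ao": y[4], "p_as": y[5], "p_vs": y[6],
            "p_po": y[7], "p_ap": y[8], "p_vp": y[9],
        }
        self.flows = dict(zip(FLOW_NAMES, algebraic_flows(t, y, p)))
        self.flows.update({"Q_ao": y[10], "Q_as": y[11], "Q_po": y[12], "Q_ap": y[13]})
        self.radii = {
            "r_lv": radius_from_volume(np.maximum(y[0], 0.0), p.lv),
            "r_rv": radius_from_volume(np.maximum(y[1], 0.0), p.rv),
            "r_la": radius_from_volume(np.maximum(y[2], 0.0), p.la),
            "r_ra": radius_from_volume(np.maximum(y[3], 0.0), p.ra),
        }
        self.diameters = {
            "d_lv": 2.0 * self.radii["r_lv"],
            "d_rv": self.radii["r_rv"],  # RV basal diameter ~ RV radius
            "d_la": 2.0 * self.radii["r_la"],
            "d_ra": 2.0 * self.radii["r_ra"],
        }

    @property
    def T(self) -> float:
        return self.params.T

    def state(self, name: str) -> np.ndarray:
        return self.states[STATE_NAMES.index(name)]

    @property
    def volumes(self) -> dict[str, np.ndarray]:
        return {n: self.states[i] for i, n in enumerate(STATE_NAMES[:4])}

    def to_dataframe(self) -> pd.DataFrame:
        """Full time-series table, one row per output time."""
        cols: dict[str, np.ndarray] = {"t": self.t}
        cols.update(self.pressures)
        cols.update({n: self.states[i] for i, n in enumerate(STATE_NAMES[:4])})
        cols.update({n: self.flows[n] for n in
                     ("Q_mv", "Q_av", "Q_tv", "Q_pv", "Q_ao", "Q_as", "Q_po", "Q_ap")})
        cols.update(self.diameters)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Write the time-series table with a units header comment line."""
        with open(path, "w") as fh:
            fh.write("# units: t [s], p_* [mmHg], V_* [mL], Q_* [mL/s], d_* [cm]; "
                     "d_rv is the RV basal diameter (= RV radius)\n")
            self.to_dataframe().to_csv(fh, index=False)


class CalibrationError(RuntimeError):
    pass


def _integrate_cycle(p, y0, t0, settings, grid):
    sol = solve_ivp(
        state_derivative, (t0, t0 + p.T), y0, args=(p,),
        method=settings.method, t_eval=grid,
        max_step=settings.max_step, rtol=settings.rel_tol, atol=settings.abs_tol,
    )
    if not sol.success:
        raise RuntimeError(
            f"stiff solver failed at t={sol.t[-1] if sol.t.size else t0:.4f}s: {sol.message}; "
            f"last valid state {sol.y[:, -1] if sol.t.size else y0}"
        )
    return sol.y


def run_to_steady_state(
    p: CirculationParams,
    init: ModelState | np.ndarray,
    settings: SolverSettings = SolverSettings(),
) -> SimulationResult:
    """Integrate cycle by cycle until periodic steady state.

    Returns the final cycle sampled at ``output_dt``.  Non-convergence
    within ``n_cycles`` is flagged on the result, not raised.
    """
    y = init.to_array() if isinstance(init, ModelState) else np.asarray(init, dtype=float)
    T = p.T
    n_grid = int(round(T / settings.output_dt))
    rel_grid = np.linspace(0.0, T, n_grid + 1)

    means: list[tuple[float, float]] = []
    converged = False
    traj = None
    cycles_run = 0
    for k in range(settings.n_cycles):
        t0 = k * T
        traj = _integrate_cycle(p, y, t0, settings, t0 + rel_grid)
        y = traj[:, -1]
        mean_vlv = float(np.trapezoid(traj[0], rel_grid) / T)
        mean_pao = float(np.trapezoid(traj[4], rel_grid) / T)
        means.append((mean_vlv, mean_pao))
        cycles_run = k + 1
        if k > 0:
            dv = abs(mean_vlv - means[-2][0]) / max(abs(means[-2][0]), 1e-12)
            dp = abs(mean_pao - means[-2][1]) / max(abs(means[-2][1]), 1e-12)
            if dv < settings.steady_tol and dp < settings.steady_tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"no periodic steady state within {settings.n_cycles} cycles "
            f"(steady_tol={settings.steady_tol})", RuntimeWarning)

    history = pd.DataFrame(means, columns=["mean_V_lv", "mean_p_ao"])
    history.index.name = "cycle"
    return SimulationResult(
        t=rel_grid, states=traj, params=p,
        converged=converged, n_cycles_run=cycles_run, cycle_history=history,
    )


def default_initial_state(p: CirculationParams, total_stressed: float) -> ModelState:
    """Deterministic feasible initial condition holding a given total volume.

    Chambers start at 1.5x their zero-pressure volume; the remaining blood
    is spread over the compliances at a single uniform pressure (i.e. split
    proportional to C); all inertance flows start at zero.
    """
    chamber_v = [1.5 * p.lv.V0, 1.5 * p.rv.V0, 1.5 * p.la.V0, 1.5 * p.ra.V0]
    remainder = total_stressed - sum(chamber_v)
    if remainder <= 0:
        raise ValueError(
            f"total stressed volume {total_stressed} mL cannot cover the chamber "
            f"starting volumes ({sum(chamber_v)} mL)")
    C_sum = p.ao.C + p.as_.C + p.vs.C + p.po.C + p.ap.C + p.vp.C
    p_uniform = remainder / C_sum
    return ModelState(
        *chamber_v,
        p_uniform, p_uniform, p_uniform, p_uniform, p_uniform, p_uniform,
        0.0, 0.0, 0.0, 0.0,
    )


def _steady_lv_edv(p, total, settings) -> tuple[float, SimulationResult]:
    res = run_to_steady_state(p, default_initial_state(p, total), settings)
    return float(res.state("V_lv").max()), res


def calibrate_total_volume(
    p: CirculationParams,
    target_lv_edv: float,
    bracket: tuple[float, float],
    settings: SolverSettings = SolverSettings(),
    edv_tol: float = 0.1,
    max_iter: int = 30,
) -> tuple[float, SimulationResult]:
    """Find the total stressed volume whose steady state hits a target LV EDV.

    Safeguarded secant iteration on the (monotone) map total volume ->
    steady-state LV EDV, falling back to bisection when the secant step
    leaves the bracket.  Stops when |EDV - target| < edv_tol (mL).
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, res_lo = _steady_lv_edv(p, lo, settings)
    if abs(f_lo - target_lv_edv) < edv_tol:
        return lo, res_lo
    f_hi, res_hi = _steady_lv_edv(p, hi, settings)
    if abs(f_hi - target_lv_edv) < edv_tol:
        return hi, res_hi
    if not (min(f_lo, f_hi) < target_lv_edv < max(f_lo, f_hi)):
        raise CalibrationError(
            f"bracket ({lo}, {hi}) mL does not straddle target LV EDV "
            f"{target_lv_edv} mL: achieved EDVs ({f_lo:.2f}, {f_hi:.2f}) mL")

    for _ in range(max_iter):
        # secant proposal, clipped well inside the bracket
        x = lo + (target_lv_edv - f_lo) * (hi - lo) / (f_hi - f_lo)
        if not (lo < x < hi):
            x = 0.5 * (lo + hi)
        f_x, res_x = _steady_lv_edv(p, x, settings)
        if abs(f_x - target_lv_edv) < edv_tol:
            return x, res_x
        if (f_x < target_lv_edv) == (f_lo < target_lv_edv):
            lo, f_lo = x, f_x
        else:
            hi, f_hi = x, f_x
    raise CalibrationError(
        f"calibration did not reach |LV EDV - {target_lv_edv}| < {edv_tol} mL "
        f"within {max_iter} iterations (bracket now ({lo:.1f}, {hi:.1f}) mL)")
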