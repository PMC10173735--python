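"""ODE model of CTL-melanoma interactions with checkpoint-driven exhaustion.

Tumor cells cycle between the G1 compartment ``G`` and the pooled
S-G2-M compartment ``S`` (both in mm^3-equivalents; tumor volume is
``V = S + G`` under the constant-density assumption).  CTLs ``E``
infiltrate from day 0, expand and die inside the tumor, kill tumor
cells, and secrete IFNG ``I``, which (i) arrests the G1 -> S-G2-M
transition through the factor ``1 / (1 + ki * I/V)`` and (ii) drives
induction of the immune checkpoints PDCD1 ``P``, CD274 ``PL``, LAG3
``L`` and HAVCR2 ``H``.  The per-CTL checkpoint load defines an
exhaustion level ``R``; CTL effector functions (killing, expansion,
IFNG secretion) are scaled by the activity ``alpha = 1/(1 + kex * R)``,
which equals 1 for unexhausted CTLs and decays to 0 as exhaustion
accumulates.

Two simulation modes exist: the full self-contained model, and an
input-forced mode in which measured CTL and IFNG time courses are
interpolated and fed to the two-state tumor equations (used for the
killing-vs-arrest grid search).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _fast
from .calibration import basal_growth_rate, steady_state_ratio
from .params import PARAM_ORDER, TumorImmuneParams

STATE_ORDER = ("S", "G", "E", "I", "P", "PL", "L", "H")

TRAJECTORY_COLUMNS = ("time", "S", "G", "E", "I", "P", "PL", "L", "H",
                      "V", "ratio_SG", "alpha", "R")


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.4g})")
        self.t_fail = t_fail


@dataclass(frozen=True)
class StateVector:
    """Instantaneous model state at time ``t`` (days after CTL transfer)."""

    S: float = 0.0
    G: float = 0.0
    E: float = 0.0
    I: float = 0.0
    P: float = 0.0
    PL: float = 0.0
    L: float = 0.0
    H: float = 0.0
    t: float = 0.0

    def __post_init__(self):
        for name in STATE_ORDER:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be >= 0")

    @property
    def V(self) -> float:
        """Tumor volume (mm^3-equivalents)."""
        return self.S + self.G

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_ORDER], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], t: float = 0.0) -> "StateVector":
        y = np.asarray(y, dtype=float)
        return cls(**dict(zip(STATE_ORDER, y)), t=t)


@dataclass(frozen=True)
class InputSignals:
    """Piecewise-linear CTL and IFNG inputs for the forced model.

    Evaluation between knots is the linear interpolant; outside the knot
    range the nearest knot value is used (clamped).
    """

    e_knots: tuple[tuple[float, float], ...]
    i_knots: tuple[tuple[float, float], ...]

    def __post_init__(self):
        for knots in (self.e_knots, self.i_knots):
            t = np.array([k[0] for k in knots])
            if len(t) < 1 or np.any(np.diff(t) <= 0):
                raise ValueError("knots must be nonempty with increasing times")

    def _arrays(self, knots):
        t = np.array([k[0] for k in knots], dtype=float)
        v = np.array([k[1] for k in knots], dtype=float)
        return t, v

    def E_of_t(self, t) -> np.ndarray | float:
        tk, vk = self._arrays(self.e_knots)
        return np.interp(t, tk, vk)

    def I_of_t(self, t) -> np.ndarray | float:
        tk, vk = self._arrays(self.i_knots)
        return np.interp(t, tk, vk)

    @classmethod
    def from_means(cls, e_days, e_means, i_days, i_means) -> "InputSignals":
        return cls(tuple(zip(map(float, e_days), map(float, e_means))),
                   tuple(zip(map(float, i_days), map(float, i_means))))


# ---------------------------------------------------------------------
# algebraic pieces

def arrest_factor(I: float, V: float, ki: float):
    """IFNG-dependent multiplier on the G1 -> S-G2-M transition.

    ``1 / (1 + ki * I / V)``: equals 1 without IFNG and decreases
    monotonically with the intratumoral IFNG concentration ``I/V``;
    ``1/ki`` is the concentration halving the transition rate.
    """
    if np.any(np.asarray(V) <= 0):
        raise ValueError("V must be positive")
    if ki < 0 or np.any(np.asarray(I) < 0):
        raise ValueError("ki and I must be nonnegative")
    return 1.0 / (1.0 + ki * np.asarray(I) / np.asarray(V))


def exhaustion_level(state: StateVector, params: TumorImmuneParams) -> float:
    """Total exhaustion ``R`` of the CTL population.

    Weighted sum of per-CTL checkpoint loads:
    ``kl*L/E + kt*H/E + kp*(P/E)*(PL/V)``.  With no CTLs present there
    are no exhausted CTLs, so ``R = 0`` when ``E = 0``.
    """
    if state.E <= 0:
        return 0.0
    r = params.kl * state.L / state.E + params.kt * state.H / state.E
    if params.kp != 0.0:
        if state.V <= 0:
            raise ValueError("V must be positive for the PDCD1*CD274 term")
        r += params.kp * (state.P / state.E) * (state.PL / state.V)
    return r


def ctl_activity(R: float, kex: float = 1.0):
    """CTL activity ``alpha = 1 / (1 + kex * R)``.

    Unexhausted CTLs (``R = 0``) are fully active; activity halves at
    ``R = 1/kex`` and vanishes as exhaustion grows without bound.  The
    factor multiplies killing, expansion and IFNG secretion.
    """
    if kex <= 0:
        raise ValueError("kex must be positive")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be nonnegative")
    out = 1.0 / (1.0 + kex * R)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------
# right-hand sides (reference implementations; compiled twins in _fast)

def rhs_basic(state: StateVector, params: TumorImmuneParams) -> np.ndarray:
    """Basal tumor growth: cycling without CTLs or IFNG.

    ``dS/dt = kgs*G - ksg*S`` and ``dG/dt = -kgs*G + 2*ksg*S`` (each
    division returns two G1 daughters).  Derivatives of all immune
    components are zero.  Returns derivatives in :data:`STATE_ORDER`.
    """
    dy = np.zeros(len(STATE_ORDER))
    dy[0] = params.kgs * state.G - params.ksg * state.S
    dy[1] = -params.kgs * state.G + 2.0 * params.ksg * state.S
    return dy


def rhs_full(state: StateVector, params: TumorImmuneParams,
             infiltration: bool = True) -> np.ndarray:
    """Full model right-hand side, all eight components.

    Killing ``alpha*ke*E`` is split between compartments in proportion
    to their share of the tumor (fractions are defined as zero for an
    empty tumor).  ``infiltration=False`` disables the ``s0*V`` source
    (pre-transfer phase, t < 0).
    """
    p = params.to_vector()
    if not infiltration:
        p[PARAM_ORDER.index("s0")] = 0.0
    dy = np.empty(len(STATE_ORDER))
    _fast.rhs_full_vec(0.0, state.to_array(), p, dy)
    return dy


# ---------------------------------------------------------------------
# simulation

def initial_state(params: TumorImmuneParams, v0: float = 100.0,
                  t0: float = 0.0) -> StateVector:
    """Pre-treatment initial condition.

    The tumor starts at the basal steady-state S:G ratio with volume
    chosen so that basal growth reaches ``v0`` at day 0 (``t0 <= 0`` is
    back-extrapolated along the basal exponential); all immune
    components start at zero.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if t0 > 0:
        raise ValueError("initial time must be at or before CTL transfer")
    g = basal_growth_rate(params.kgs, params.ksg)
    r = steady_state_ratio(params.kgs, params.ksg)
    v_t0 = v0 * np.exp(g * t0)
    s = v_t0 * r / (1.0 + r)
    return StateVector(S=s, G=v_t0 - s, t=t0)


def _trajectory_frame(times, ys, params, forced_alpha=None) -> pd.DataFrame:
    ys = np.asarray(ys, dtype=float)
    df = pd.DataFrame(ys, columns=list(STATE_ORDER))
    df.insert(0, "time", np.asarray(times, dtype=float))
    df["V"] = df["S"] + df["G"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio_SG"] = np.where(df["G"] > 0, df["S"] / df["G"], np.nan)
    if forced_alpha is not None:
        df["alpha"] = forced_alpha
        df["R"] = 0.0
        return df
    R = np.zeros(len(df))
    pos = df["E"].to_numpy() > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        E = df["E"].to_numpy()
        V = df["V"].to_numpy()
        R[pos] = (params.kl * df["L"].to_numpy()[pos] / E[pos]
                  + params.kt * df["H"].to_numpy()[pos] / E[pos]
                  + params.kp * (df["P"].to_numpy()[pos] / E[pos])
                  * np.where(V[pos] > 0, df["PL"].to_numpy()[pos] / V[pos], 0.0))
    df["R"] = R
    df["alpha"] = 1.0 / (1.0 + params.kex * R)
    return df


def simulate(params: TumorImmuneParams, init: StateVector, times,
             inputs: InputSignals | None = None, rtol: float = 1e-8,
             atol: float = 1e-10, method: str = "LSODA") -> pd.DataFrame:
    """Integrate the model over ``times`` (strictly increasing days).

    Without ``inputs`` the full eight-state model is integrated (CTL
    infiltration switches on at day 0).  With ``inputs`` the CTL and
    IFNG equations are disabled and their interpolated time courses
    drive the two tumor equations.  Returns a tidy trajectory frame with
    columns :data:`TRAJECTORY_COLUMNS`.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if init.t > times[0]:
        raise ValueError("initial state must be at or before the first output time")
    t0 = float(init.t)

    if inputs is not None:
        def f(t, y):
            dy = np.empty(2)
            tE, vE = inputs._arrays(inputs.e_knots)
            tI, vI = inputs._arrays(inputs.i_knots)
            _fast.rhs_forced_vec(t, y, params.ke, params.ki, params.kgs,
                                 params.ksg, tE, vE, tI, vI, dy)
            return dy

        y0 = np.array([init.S, init.G])
        sol = solve_ivp(f, (t0, times[-1]), y0, t_eval=times, method=method,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(sol.message, sol.t[-1] if len(sol.t) else t0)
        y = np.clip(sol.y.T, 0.0, None)
        full = np.zeros((len(times), len(STATE_ORDER)))
        full[:, 0:2] = y
        full[:, 2] = inputs.E_of_t(times)
        full[:, 3] = inputs.I_of_t(times)
        return _trajectory_frame(times, full, params,
                                 forced_alpha=np.ones(len(times)))

    p = params.to_vector()
    s0_idx = PARAM_ORDER.index("s0")

    def f_on(t, y):
        dy = np.empty(len(STATE_ORDER))
        _fast.rhs_full_vec(max(t, 0.0), y, p, dy)
        return dy

    def f_off(t, y):
        p_off = p.copy()
        p_off[s0_idx] = 0.0
        dy = np.empty(len(STATE_ORDER))
        _fast.rhs_full_vec(t, y, p_off, dy)
        return dy

    y0 = init.to_array()
    out = np.empty((len(times), len(STATE_ORDER)))
    filled = 0
    t_cur = t0
    # integrate the pre-transfer phase (no infiltration) up to day 0
    if t_cur < 0 and times[-1] > 0:
        pre_times = times[times <= 0]
        eval_pts = np.unique(np.append(pre_times, 0.0))
        sol = solve_ivp(f_off, (t_cur, 0.0), y0, t_eval=eval_pts,
                        method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(sol.message, sol.t[-1] if len(sol.t) else t_cur)
        if len(pre_times):
            out[: len(pre_times)] = sol.y.T[: len(pre_times)]
            filled = len(pre_times)
        y0 = sol.y[:, -1]
        t_cur = 0.0
    rest = times[filled:]
    if len(rest):
        fun = f_off if times[-1] <= 0 else f_on
        sol = solve_ivp(fun, (t_cur, rest[-1]), np.clip(y0, 0.0, None),
                        t_eval=rest, method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(sol.message, sol.t[-1] if len(sol.t) else t_cur)
        out[filled:] = sol.y.T
    out = np.clip(out, 0.0, None)
    return _trajectory_frame(times, out, params)


def simulate_fast(params: TumorImmuneParams, init: StateVector, times,
                  rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Raw-state trajectory via the compiled integrator (fitting path).

    Returns an ``(len(times), 8)`` array; raises
    :class:`SimulationError` on solver failure.
    """
    times = np.asarray(times, dtype=float)
    ys, status = _fast.integrate_full(params.to_vector(), init.to_array(),
                                      float(init.t), times, rtol, atol, 200000)
    if status != _fast.STATUS_OK:
        raise SimulationError(f"compiled integration failed (status {status})",
                              float(times[-1]))
    return ys
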