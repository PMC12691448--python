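"""Piecewise ODE integration of the treatment model across bolus doses.

Integration runs segment by segment between consecutive dose days with a
stiff-capable adaptive solver; at each dose day the drug compartments jump
by the administered amount and integration restarts from the post-jump
state (left-limit convention). The ε(0) of the dynamic model is the
pre-treatment quasi-steady state, computed before any day-0 bolus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dosing import AVELUMAB, TreatmentArm
from .model import epsilon_qss_init
from .params import BaseParams, EpsilonParams

__all__ = ["Trajectory", "simulate", "final_outcome",
           "CONSTANT_EPS", "DYNAMIC_EPS"]

CONSTANT_EPS = "constant_eps"
DYNAMIC_EPS = "dynamic_eps"

# Negative excursions smaller than this (absolute) are solver noise and are
# clipped to zero; anything larger indicates a tolerance failure and raises.
_NEG_CLIP = 1e-8


@dataclass
class Trajectory:
    """Dense simulated path of one treatment arm.

    ``times`` is strictly increasing and contains every dose day; the state
    stored at a dose day is the post-jump value, with the left limit kept in
    ``pre_jump`` (day → state row). Columns of ``states``:
    V, T, A1, A2, eps.
    """

    times: np.ndarray
    states: np.ndarray
    arm: TreatmentArm
    mode: str
    pre_jump: Dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def V(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def A1(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def A2(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def eps(self) -> np.ndarray:
        return self.states[:, 4]

    def volume_at(self, days: np.ndarray) -> np.ndarray:
        """Tumor volume linearly interpolated at the requested days."""
        days = np.asarray(days, dtype=float)
        if days.min() < self.times[0] - 1e-12 or days.max() > self.times[-1] + 1e-12:
            raise ValueError("requested days lie outside the simulated window "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return np.interp(days, self.times, self.V)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_day": self.times,
            "V_mm3": self.V, "T_mm3": self.T,
            "A1": self.A1, "A2": self.A2, "eps": self.eps,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs(bp: BaseParams, ep: Optional[EpsilonParams], dynamic: bool,
         const_eps: float):
    """Vectorized right-hand side over y = (V, T, A1, A2[, eps]).

    Negative components are clamped to zero for rate evaluation only; the
    solver's own y is untouched (tiny excursions are handled after the
    fact by `_clip_negative`).
    """
    r, eta, delta, lam, d_T = bp.r, bp.eta, bp.delta, bp.lambda_T, bp.d_T
    c1, c2, KA1, KA2 = bp.c1, bp.c2, bp.K_A1, bp.K_A2
    KTQ, q0, dA1, dA2 = bp.K_TQ, bp.q0, bp.d_A1, bp.d_A2

    def f(t, y):
        v = y[0] if y[0] > 0 else 0.0
        tc = y[1] if y[1] > 0 else 0.0
        a1 = y[2] if y[2] > 0 else 0.0
        a2 = y[3] if y[3] > 0 else 0.0
        eps = (y[4] if y[4] > 0 else 0.0) if dynamic else const_eps

        phi = c1 * a1 / (c1 * a1 + KA1)
        a2sat = c2 * a2 / (KA2 + c2 * a2)
        q = q0 * tc * (tc + eps * v) * (1.0 - phi)
        F = (delta + lam * tc * a2sat) / (1.0 + q / KTQ)

        dv = r * v - eta * v * tc
        dt = F - d_T * tc
        out = [dv, dt, -dA1 * a1, -dA2 * a2]
        if dynamic:
            vsat = v / (ep.K_V + v)
            deps = (ep.k_basal * vsat + ep.alpha_A2 * vsat * a2sat
                    - ep.alpha_A1 * phi * eps - ep.d_eps * eps)
            out.append(deps)
        return out

    return f


def _clip_negative(y: np.ndarray, where: str) -> np.ndarray:
    bad = y < -_NEG_CLIP
    if np.any(bad):
        raise RuntimeError(f"integration produced negative state "
                           f"(min {y.min():.3e}) in {where}; "
                           "tighten solver tolerances")
    return np.maximum(y, 0.0)


def simulate(bp: BaseParams,
             eps: Union[EpsilonParams, float],
             arm: TreatmentArm,
             t_end: float = 25.0,
             mode: Optional[str] = None,
             v0: float = 100.0,
             t0_cells: Optional[float] = None,
             grid_step: float = 0.1,
             t_eval: Optional[np.ndarray] = None,
             rtol: float = 1e-8,
             atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Simulate one treatment arm.

    Parameters
    ----------
    eps
        An :class:`EpsilonParams` (dynamic-ε mode, five ODEs, ε(0) set to
        the pre-treatment quasi-steady state) or a scalar (constant-ε mode,
        four ODEs with ε held fixed).
    mode
        ``"dynamic_eps"`` or ``"constant_eps"``; inferred from the type of
        ``eps`` when omitted.
    v0, t0_cells
        Initial tumor volume (default 100 mm³) and T-cell volume; the
        T-cell default δ/d_T is the drug-free basal production/decay
        balance.
    t_eval
        Explicit output times (must include 0 and t_end bracketing the
        observations); defaults to a dense grid of ``grid_step`` days with
        every dose day inserted.
    """
    if mode is None:
        mode = DYNAMIC_EPS if isinstance(eps, EpsilonParams) else CONSTANT_EPS
    if mode not in (CONSTANT_EPS, DYNAMIC_EPS):
        raise ValueError(f"unknown mode {mode!r}")
    dynamic = mode == DYNAMIC_EPS
    if dynamic and not isinstance(eps, EpsilonParams):
        raise TypeError("dynamic mode needs EpsilonParams")
    if not dynamic:
        const_eps = float(eps)
        if const_eps < 0:
            raise ValueError("constant eps must be nonnegative")
    if not (t_end > 0 and v0 > 0):
        raise ValueError("t_end and v0 must be positive")
    if t0_cells is None:
        t0_cells = bp.delta / bp.d_T

    dose_days = [d for d in arm.dose_days if d < t_end]
    if t_eval is None:
        grid = np.arange(0.0, t_end + grid_step / 2, grid_step)
        grid = np.unique(np.concatenate([grid, dose_days, [t_end]]))
    else:
        grid = np.unique(np.asarray(t_eval, dtype=float))
        grid = np.unique(np.concatenate([grid, dose_days, [0.0, t_end]]))

    # dynamic ε(0): drug-free quasi-steady state, before any day-0 bolus
    if dynamic:
        y = np.array([v0, t0_cells, 0.0, 0.0, epsilon_qss_init(v0, eps)])
        ep = eps
    else:
        y = np.array([v0, t0_cells, 0.0, 0.0])
        ep = None
    rhs = _rhs(bp, ep, dynamic, 0.0 if dynamic else const_eps)

    breakpoints = sorted(set(dose_days) | {0.0, t_end})
    times_out, states_out, pre_jump = [], [], {}

    pending = {d: [e for e in arm.events if e.day == d] for d in dose_days}

    # apply any day-0 doses after recording the pre-treatment state
    def _apply(day, yvec):
        pre_jump[day] = yvec.copy()
        for e in pending[day]:
            idx = 2 if e.drug == AVELUMAB else 3
            yvec = yvec.copy()
            yvec[idx] += e.amount
        return yvec

    if 0.0 in pending:
        y = _apply(0.0, y)
    times_out.append(0.0)
    states_out.append(y.copy())

    segments = [(breakpoints[i], breakpoints[i + 1])
                for i in range(len(breakpoints) - 1)]
    for t_a, t_b in segments:
        seg_eval = grid[(grid > t_a) & (grid <= t_b)]
        if seg_eval.size == 0 or seg_eval[-1] != t_b:
            seg_eval = np.append(seg_eval, t_b)
        sol = solve_ivp(rhs, (t_a, t_b), y, method=method,
                        t_eval=seg_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed on segment "
                               f"[{t_a}, {t_b}] for arm {arm.name!r}: "
                               f"{sol.message}")
        ys = _clip_negative(sol.y.T, f"segment [{t_a}, {t_b}]")
        y = ys[-1].copy()
        # interior points; the endpoint state may be replaced by its
        # post-jump value below
        times_out.extend(sol.t[:-1])
        states_out.extend(ys[:-1])
        if t_b in pending:
            y = _apply(t_b, y)
        times_out.append(t_b)
        states_out.append(y.copy())

    times = np.asarray(times_out)
    states = np.vstack(states_out)
    if not dynamic:
        states = np.column_stack([states, np.full(len(times), const_eps)])
    return Trajectory(times=times, states=states, arm=arm, mode=mode,
                      pre_jump=pre_jump)


def final_outcome(traj: Trajectory,
                  elimination_threshold: float = 1.0) -> Tuple[str, float]:
    """Classify the end state: eliminated iff final V < threshold (strict)."""
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    v_end = float(traj.V[-1])
    return ("eliminated" if v_end < elimination_threshold else "progressing",
            v_end)
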