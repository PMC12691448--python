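"""Model equations: blockade, complex, T-cell activation, and the ε ODE.

The system tracks tumor volume V (mm³), effector T-cell volume T (mm³), the
anti-PD-L1 antibody Avelumab A1 (μg-equivalent), the immunocytokine
NHS-muIL12 A2 (μg-equivalent) and — in the refined model — the tumor's
functional immunosuppressive strength ε (dimensionless, an effective PD-L1
expression propensity).

Continuous dynamics (dosing enters as state jumps, see :mod:`pdl1dyn.dosing`):

    dV/dt  = r V − η V T
    dT/dt  = F(V, T, A1, A2) − d_T T
    dA1/dt = −d_A1 A1
    dA2/dt = −d_A2 A2
    dε/dt  = k_basal V/(K_V+V) + α_A2 V/(K_V+V) · c2 A2/(K_A2+c2 A2)
             − α_A1 φ(A1) ε − d_ε ε

with the Avelumab blockade fraction φ(A1) = c1 A1/(c1 A1 + K_A1), the
PD-1/PD-L1 complex Q = q0 T (T + εV)(1 − φ) and the activation function
F = (δ + λ_T T · c2 A2/(K_A2 + c2 A2)) / (1 + Q/K_TQ).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .params import BaseParams, EpsilonParams, decay_rate_from_half_life

__all__ = [
    "SystemState",
    "blockade_fraction",
    "complex_Q",
    "activation_F",
    "base_rhs",
    "epsilon_rhs",
    "epsilon_qss_init",
    "decay_rate_from_half_life",
]


@dataclass(frozen=True)
class SystemState:
    """One point of the system: (V, T, A1, A2) plus ε in dynamic mode."""

    V: float
    T: float
    A1: float
    A2: float
    eps: Optional[float] = None

    def __post_init__(self) -> None:
        comps = [self.V, self.T, self.A1, self.A2]
        if self.eps is not None:
            comps.append(self.eps)
        arr = np.asarray(comps, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state {self}")
        if np.any(arr < 0):
            raise ValueError(f"negative state component in {self}")

    def as_array(self) -> np.ndarray:
        if self.eps is None:
            return np.array([self.V, self.T, self.A1, self.A2])
        return np.array([self.V, self.T, self.A1, self.A2, self.eps])


def _require_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and nonnegative, got {v}")


def blockade_fraction(a1: float, params: BaseParams) -> float:
    """Fraction of PD-1/PD-L1 complex formation blocked by Avelumab.

    φ(A1) = c1·A1 / (c1·A1 + K_A1): a Michaelis–Menten response, zero with
    no drug, 1/2 when the effective concentration c1·A1 equals K_A1, and
    saturating strictly below 1.
    """
    _require_nonneg(a1=a1)
    x = params.c1 * a1
    return x / (x + params.K_A1)


def complex_Q(v: float, t: float, a1: float, eps: float,
              params: BaseParams) -> float:
    """Abundance of the inhibitory PD-1/PD-L1 complex.

    Q = q0·T·(T + ε·V)·(1 − φ(A1)). PD-1 sits on T-cells; PD-L1 on both
    T-cells and (scaled by ε) tumor cells, so complex formation grows with
    both populations and is relieved by Avelumab blockade.
    """
    _require_nonneg(v=v, t=t, a1=a1, eps=eps)
    return params.q0 * t * (t + eps * v) * (1.0 - blockade_fraction(a1, params))


def activation_F(v: float, t: float, a1: float, a2: float, eps: float,
                 params: BaseParams) -> float:
    """T-cell production rate (mm³·day⁻¹).

    Basal production δ plus saturating NHS-muIL12 stimulation proportional
    to T, the whole suppressed by the checkpoint complex through
    1/(1 + Q/K_TQ).
    """
    _require_nonneg(v=v, t=t, a1=a1, a2=a2, eps=eps)
    stim = params.lambda_T * t * (params.c2 * a2) / (params.K_A2 + params.c2 * a2)
    q = complex_Q(v, t, a1, eps, params)
    return (params.delta + stim) / (1.0 + q / params.K_TQ)


def base_rhs(state: SystemState, params: BaseParams,
             eps: float) -> Tuple[float, float, float, float]:
    """Time derivatives (dV, dT, dA1, dA2) of the four-compartment system.

    Drug administration is impulsive, so the continuous right-hand side
    contains only first-order clearance for A1 and A2.
    """
    v, t, a1, a2 = state.V, state.T, state.A1, state.A2
    _require_nonneg(eps=eps)
    dv = params.r * v - params.eta * v * t
    dt = activation_F(v, t, a1, a2, eps, params) - params.d_T * t
    return (dv, dt, -params.d_A1 * a1, -params.d_A2 * a2)


def epsilon_rhs(eps: float, v: float, a1: float, a2: float,
                ep: EpsilonParams, bp: BaseParams) -> float:
    """dε/dt: basal + NHS-muIL12-driven production − Avelumab-mediated
    suppression − natural decay.

    Production saturates in tumor volume with half-saturation K_V;
    the drug terms reuse the same Michaelis–Menten saturations as the
    base system (φ for Avelumab, the c2·A2 curve for NHS-muIL12).
    """
    _require_nonneg(eps=eps, v=v, a1=a1, a2=a2)
    vsat = v / (ep.K_V + v) if v > 0 else 0.0
    a2sat = (bp.c2 * a2) / (bp.K_A2 + bp.c2 * a2) if a2 > 0 else 0.0
    phi = blockade_fraction(a1, bp)
    return (ep.k_basal * vsat
            + ep.alpha_A2 * vsat * a2sat
            - ep.alpha_A1 * phi * eps
            - ep.d_eps * eps)


def epsilon_qss_init(v0: float, ep: EpsilonParams) -> float:
    """Pre-treatment quasi-steady-state value of ε at tumor volume v0.

    Before treatment ε equilibrates between basal production and natural
    decay: ε(0) = (k_basal/d_ε) · v0/(K_V + v0). ``epsilon_rhs`` vanishes
    at this value when no drug is present.
    """
    _require_nonneg(v0=v0)
    return (ep.k_basal / ep.d_eps) * v0 / (ep.K_V + v0)
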