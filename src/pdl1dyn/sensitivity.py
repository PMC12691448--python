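"""Local ±25% parameter sensitivity of the dynamic-ε model.

Each of the nine mechanism and pharmacokinetic constants that were not
refit from the tumor-growth data — the five ε-equation constants
(k_basal, K_V, alpha_A1, alpha_A2, d_eps), the drug half-saturations
(K_A1, K_A2) and the clearance rates (d_A1, d_A2) — is perturbed one at a
time by ±25% and every treatment arm re-simulated; the change in final
tumor volume and the elimination/progression outcome are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dosing import TreatmentArm, standard_arms
from .params import BaseParams, EpsilonParams
from .simulate import DYNAMIC_EPS, Trajectory, final_outcome, simulate

__all__ = ["SWEEP_PARAMS", "SensitivityRecord", "local_sweep",
           "timecourse_sensitivity", "most_sensitive_arm", "sweep_frame"]

#: The nine fixed constants swept by default.
SWEEP_PARAMS = ("k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps",
                "K_A1", "K_A2", "d_A1", "d_A2")

_EPS_FIELDS = {"k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps"}
_BASE_FIELDS = {"K_A1", "K_A2", "d_A1", "d_A2"}


@dataclass
class SensitivityRecord:
    """One perturbed simulation: parameter, signed fraction, arm, outcome."""

    parameter: str
    perturbation: float
    arm: str
    final_volume: float
    outcome: str
    nominal_final_volume: float

    @property
    def rel_change(self) -> float:
        ref = max(self.nominal_final_volume, 1e-12)
        return (self.final_volume - self.nominal_final_volume) / ref


def _perturbed(bp: BaseParams, ep: EpsilonParams, name: str, frac: float):
    if name in _EPS_FIELDS:
        return bp, ep.replace(**{name: getattr(ep, name) * (1.0 + frac)})
    if name in _BASE_FIELDS or hasattr(bp, name):
        return bp.replace(**{name: getattr(bp, name) * (1.0 + frac)}), ep
    raise ValueError(f"unknown parameter {name!r}")


def local_sweep(bp: BaseParams, ep: EpsilonParams,
                parameters: Sequence[str] = SWEEP_PARAMS,
                frac: float = 0.25,
                arms: Optional[Sequence[TreatmentArm]] = None,
                t_end: float = 25.0, v0: float = 100.0,
                elimination_threshold: float = 1.0
                ) -> List[SensitivityRecord]:
    """±frac one-at-a-time sweep over all parameters × arms.

    Defaults give 9 parameters × 2 signs × 6 arms = 108 records.
    """
    if not (0 <= frac < 1):
        raise ValueError("frac must be in [0, 1)")
    if arms is None:
        arms = standard_arms("EMT6")
    for p in parameters:
        _perturbed(bp, ep, p, 0.1)  # validate names up front

    nominal_final = {}
    for arm in arms:
        traj = simulate(bp, ep, arm, t_end=t_end, mode=DYNAMIC_EPS, v0=v0)
        nominal_final[arm.name] = final_outcome(traj, elimination_threshold)[1]

    records = []
    for p in parameters:
        for sign in (+1.0, -1.0):
            bp2, ep2 = _perturbed(bp, ep, p, sign * frac)
            for arm in arms:
                traj = simulate(bp2, ep2, arm, t_end=t_end,
                                mode=DYNAMIC_EPS, v0=v0)
                outcome, vf = final_outcome(traj, elimination_threshold)
                records.append(SensitivityRecord(
                    parameter=p, perturbation=sign * frac, arm=arm.name,
                    final_volume=vf, outcome=outcome,
                    nominal_final_volume=nominal_final[arm.name]))
    return records


def most_sensitive_arm(records: Sequence[SensitivityRecord]) -> str:
    """Arm with the largest absolute relative change in final volume
    across all perturbations (the sensitivity-ranking statistic)."""
    worst: Dict[str, float] = {}
    for r in records:
        worst[r.arm] = max(worst.get(r.arm, 0.0), abs(r.rel_change))
    return max(worst, key=worst.get)


def timecourse_sensitivity(param: str, arm: TreatmentArm,
                           bp: BaseParams, ep: EpsilonParams,
                           frac: float = 0.25, t_end: float = 25.0,
                           v0: float = 100.0,
                           elimination_threshold: float = 1.0) -> dict:
    """Nominal vs ±frac trajectories of one parameter on one arm.

    Returns the three `Trajectory` objects on a shared dense grid plus the
    elimination/progression classification of each.
    """
    out = {}
    for label, f in (("nominal", 0.0), ("plus", frac), ("minus", -frac)):
        bp2, ep2 = _perturbed(bp, ep, param, f) if f else (bp, ep)
        traj = simulate(bp2, ep2, arm, t_end=t_end, mode=DYNAMIC_EPS, v0=v0)
        out[label] = {"trajectory": traj,
                      "outcome": final_outcome(traj, elimination_threshold)[0]}
    return out


def sweep_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    """Long-format table (parameter, sign, arm, final_V, outcome)."""
    return pd.DataFrame([{
        "parameter": r.parameter,
        "perturbation": r.perturbation,
        "arm": r.arm,
        "final_V_mm3": r.final_volume,
        "outcome": r.outcome,
        "rel_change_vs_nominal": r.rel_change,
    } for r in records])
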