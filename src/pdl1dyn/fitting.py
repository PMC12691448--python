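"""SSE trajectory fitting: per-arm constant-ε and global dynamic-ε fits.

Two estimation procedures are supported, mirroring the study's two model
variants:

* ``fit_constant_epsilon`` — the base four-ODE model with ε held constant;
  one scalar ε fitted per treatment arm (k = 1 per fit).
* ``fit_dynamic_global`` — the five-ODE model with dynamic ε; the five
  constants of the ε equation fitted simultaneously against all six arms
  (k = 5, or 4 with K_V held fixed).

Both minimize the unweighted sum of squared residuals between observed and
simulated tumor volumes (tumor volume is the only observed state) with a
bounded trust-region nonlinear least-squares optimizer, multistarted from
log-uniform Latin-hypercube points inside the bounds (the geometric center
of the bounds box is always included as the first start).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dosing import AVELUMAB, NHS_MUIL12, TreatmentArm, standard_arms
from .model import epsilon_qss_init
from .params import BaseParams, EpsilonParams
from .selection import aic
from .simulate import CONSTANT_EPS, DYNAMIC_EPS, Trajectory, simulate

__all__ = ["ArmDataset", "FitResult", "IdentifiabilityError", "sse",
           "fit_constant_epsilon", "fit_dynamic_global",
           "read_study_csv", "write_study_csv",
           "DYNAMIC_PARAM_NAMES", "default_bounds"]

#: ε-equation parameters estimated by the global dynamic fit, in order.
DYNAMIC_PARAM_NAMES = ("k_basal", "K_V", "alpha_A1", "alpha_A2", "d_eps")

#: Default bounds: nominal scale × [1e-4, 1e4] (positivity + numeric safety).
BOUNDS_SPAN = 1e4


class IdentifiabilityError(RuntimeError):
    """Raised when the requested fit is structurally unidentifiable."""


@dataclass(frozen=True)
class ArmDataset:
    """Observed tumor volumes of one treatment arm."""

    arm: TreatmentArm
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        vols = np.asarray(self.volumes, dtype=float)
        if days.shape != vols.shape or days.ndim != 1:
            raise ValueError("days and volumes must be equal-length 1-D arrays")
        if np.any(np.diff(days) < 0):
            raise ValueError("observation days must be nondecreasing")
        if np.any(vols < 0) or not np.all(np.isfinite(vols)):
            raise ValueError("volumes must be finite and nonnegative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "volumes", vols)

    @property
    def n(self) -> int:
        return len(self.days)


@dataclass
class FitResult:
    """Point estimates plus the fit diagnostics used for model comparison."""

    estimates: Dict[str, float]
    rss: float
    n: int
    k: int
    aic: float
    converged: bool
    n_starts: int
    seed: int
    mode: str
    start_costs: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "estimates": dict(self.estimates),
                "rss": self.rss, "n": self.n, "k": self.k, "aic": self.aic,
                "converged": self.converged, "n_starts": self.n_starts,
                "seed": self.seed}


def sse(observed: ArmDataset, simulated: Trajectory) -> float:
    """Residual sum of squares between observed volumes and the simulated
    tumor-volume curve interpolated at the observation days."""
    pred = simulated.volume_at(observed.days)
    return float(np.sum((observed.volumes - pred) ** 2))


def default_bounds(nominal: Union[float, Dict[str, float]],
                   span: float = BOUNDS_SPAN):
    """[nominal/span, nominal·span] per parameter."""
    if isinstance(nominal, dict):
        return {k: (v / span, v * span) for k, v in nominal.items()}
    return (nominal / span, nominal * span)


def _multistart_log10(bounds: Sequence[Tuple[float, float]], n_starts: int,
                      seed: int) -> np.ndarray:
    """Start points in log10 space: bounds-box center first, then LHS."""
    lo = np.log10([b[0] for b in bounds])
    hi = np.log10([b[1] for b in bounds])
    center = (lo + hi) / 2.0
    pts = [center]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
        u = sampler.random(n_starts - 1)
        pts.extend(lo + u * (hi - lo))
    return np.vstack(pts)


#: Residual magnitude substituted when a trial point cannot be simulated
#: (integrator failure at extreme parameters); steers the trust region
#: away without aborting the start.
_PENALTY_RESIDUAL = 1e8


def _robust(residual_fn, n_res):
    def wrapped(x):
        try:
            r = residual_fn(x)
        except (RuntimeError, ValueError, OverflowError):
            return np.full(n_res, _PENALTY_RESIDUAL)
        if not np.all(np.isfinite(r)):
            return np.full(n_res, _PENALTY_RESIDUAL)
        return r
    return wrapped


def _run_multistart(residual_fn, bounds, n_starts, seed, n_res):
    """Bounded trust-region least squares from each start; keep the best."""
    starts = _multistart_log10(bounds, n_starts, seed)
    lo = np.log10([b[0] for b in bounds])
    hi = np.log10([b[1] for b in bounds])
    fn = _robust(residual_fn, n_res)
    best = None
    best_success = False
    start_costs = []
    for x0 in starts:
        res = least_squares(fn, x0, bounds=(lo, hi),
                            method="trf", x_scale="jac",
                            xtol=1e-10, ftol=1e-10, gtol=1e-10,
                            max_nfev=2000)
        start_costs.append(2.0 * res.cost)  # cost = rss/2
        if best is None or res.cost < best.cost:
            best = res
            best_success = res.success
    if best is None or best.cost >= 0.5 * _PENALTY_RESIDUAL ** 2:
        raise RuntimeError("all multistarts failed to produce a simulable fit")
    return best, best_success, start_costs


def fit_constant_epsilon(data: ArmDataset, bp: BaseParams,
                         bounds: Optional[Tuple[float, float]] = None,
                         n_starts: int = 20, seed: int = 0,
                         v0: float = 100.0, t_end: Optional[float] = None,
                         t0_cells: Optional[float] = None) -> FitResult:
    """Fit the scalar ε of the constant-ε model to one arm (k = 1)."""
    if data.n < 2:
        raise ValueError("need at least 2 observations to fit epsilon")
    if t_end is None:
        t_end = float(max(data.days.max(), 1.0)) + 1e-9
    if bounds is None:
        bounds = default_bounds(epsilon_qss_init(v0, EpsilonParams()))

    def residual(x):
        eps = 10.0 ** x[0]
        traj = simulate(bp, eps, data.arm, t_end=t_end, mode=CONSTANT_EPS,
                        v0=v0, t0_cells=t0_cells, t_eval=data.days)
        return traj.volume_at(data.days) - data.volumes

    best, ok, costs = _run_multistart(residual, [bounds], n_starts, seed,
                                      data.n)
    rss = float(2.0 * best.cost)
    return FitResult(estimates={"eps": float(10.0 ** best.x[0])},
                     rss=rss, n=data.n, k=1,
                     aic=aic(rss, data.n, 1), converged=ok,
                     n_starts=n_starts, seed=seed, mode=CONSTANT_EPS,
                     start_costs=costs)


def _check_dynamic_identifiability(datasets: Sequence[ArmDataset],
                                   names: Sequence[str]) -> None:
    has_av = any(e.drug == AVELUMAB for d in datasets for e in d.arm.events)
    has_nhs = any(e.drug == NHS_MUIL12 for d in datasets for e in d.arm.events)
    problems = []
    if "alpha_A1" in names and not has_av:
        problems.append("alpha_A1 (no arm administers Avelumab)")
    if "alpha_A2" in names and not has_nhs:
        problems.append("alpha_A2 (no arm administers NHS-muIL12)")
    if problems:
        raise IdentifiabilityError(
            "structurally unidentifiable parameters: " + "; ".join(problems))


def fit_dynamic_global(datasets: Sequence[ArmDataset], bp: BaseParams,
                       bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                       n_starts: int = 20, seed: int = 0,
                       fit_KV: bool = True,
                       K_V_fixed: Optional[float] = None,
                       v0: float = 100.0, t_end: Optional[float] = None,
                       t0_cells: Optional[float] = None,
                       require_six_arms: bool = True) -> FitResult:
    """Simultaneously fit the ε-equation constants against all arms.

    The joint SSE over every (arm, day) residual is minimized over
    (k_basal, K_V, alpha_A1, alpha_A2, d_eps) — or over the other four
    with K_V fixed at ``K_V_fixed`` when ``fit_KV`` is off — so k is 5
    or 4 accordingly.
    """
    if require_six_arms and len(datasets) != 6:
        raise ValueError(f"expected 6 arms, got {len(datasets)} "
                         "(pass require_six_arms=False to override)")
    if any(d.n < 2 for d in datasets):
        raise ValueError("every arm needs at least 2 observations")

    names = list(DYNAMIC_PARAM_NAMES)
    nominal = EpsilonParams()
    if not fit_KV:
        names.remove("K_V")
        if K_V_fixed is None:
            K_V_fixed = nominal.K_V
    _check_dynamic_identifiability(datasets, names)

    if bounds is None:
        bounds = default_bounds(
            {nm: getattr(nominal, nm) for nm in names})
    blist = [bounds[nm] for nm in names]
    if t_end is None:
        t_end = float(max(d.days.max() for d in datasets)) + 1e-9

    def make_ep(x) -> EpsilonParams:
        kw = {nm: float(10.0 ** xi) for nm, xi in zip(names, x)}
        if not fit_KV:
            kw["K_V"] = float(K_V_fixed)
        return EpsilonParams(**kw)

    def residual(x):
        ep = make_ep(x)
        res = []
        for d in datasets:
            traj = simulate(bp, ep, d.arm, t_end=t_end, mode=DYNAMIC_EPS,
                            v0=v0, t0_cells=t0_cells, t_eval=d.days)
            res.append(traj.volume_at(d.days) - d.volumes)
        return np.concatenate(res)

    n_res = sum(d.n for d in datasets)
    best, ok, costs = _run_multistart(residual, blist, n_starts, seed, n_res)
    rss = float(2.0 * best.cost)
    n = n_res
    k = len(names)
    estimates = {nm: float(10.0 ** xi) for nm, xi in zip(names, best.x)}
    if not fit_KV:
        estimates["K_V"] = float(K_V_fixed)
    return FitResult(estimates=estimates, rss=rss, n=n, k=k,
                     aic=aic(rss, n, k), converged=ok,
                     n_starts=n_starts, seed=seed, mode=DYNAMIC_EPS,
                     start_costs=costs)


# ---------------------------------------------------------------------------
# study CSV I/O (header: arm,day,volume_mm3)

def write_study_csv(datasets: Sequence[ArmDataset], path) -> None:
    rows = [(d.arm.name, day, vol)
            for d in datasets for day, vol in zip(d.days, d.volumes)]
    pd.DataFrame(rows, columns=["arm", "day", "volume_mm3"]).to_csv(
        path, index=False)


def read_study_csv(path, study: str = "EMT6") -> List[ArmDataset]:
    """Read an ``arm,day,volume_mm3`` CSV into per-arm datasets.

    Arm labels must come from the standard arm library of ``study``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["arm", "day", "volume_mm3"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {','.join(expected)}, "
                         f"got {','.join(map(str, df.columns))}")
    for col in ("day", "volume_mm3"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after header
            raise ValueError(f"{path}: non-numeric {col!r} at line {line}")
    arms = {a.name: a for a in standard_arms(study)}
    out = []
    for name, grp in df.groupby("arm", sort=True):
        if name not in arms:
            raise ValueError(f"{path}: unknown arm label {name!r}")
        grp = grp.sort_values("day")
        out.append(ArmDataset(arm=arms[name],
                              days=grp["day"].to_numpy(float),
                              volumes=grp["volume_mm3"].to_numpy(float)))
    return out
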