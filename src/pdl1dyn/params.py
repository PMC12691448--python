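"""Parameter containers for the tumor–immune checkpoint model.

Two parameter sets drive the model: :class:`BaseParams` holds the rate and
saturation constants of the four-compartment system (tumor volume V, effector
T-cells T, Avelumab A1, NHS-muIL12 A2), and :class:`EpsilonParams` holds the
five constants of the dynamic PD-L1 expression equation for the fifth state
variable ``eps``.

Units: time in days, volumes in mm³, drug amounts in μg. The scale factors
``c1``/``c2`` convert administered μg to the effective-concentration scale on
which the half-saturation constants ``K_A1``/``K_A2`` are expressed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "BaseParams",
    "EpsilonParams",
    "decay_rate_from_half_life",
    "load_params",
    "dump_params",
    "AVELUMAB_HALF_LIFE_DAYS",
    "NHS_MUIL12_HALF_LIFE_DAYS",
]

#: Murine serum half-lives (days): Avelumab ≈ 44.6 h, NHS-muIL12 ≈ 9.5 d.
AVELUMAB_HALF_LIFE_DAYS = 1.86
NHS_MUIL12_HALF_LIFE_DAYS = 9.5


def decay_rate_from_half_life(t_half: float) -> float:
    """First-order clearance rate (day⁻¹) from a half-life in days.

    ``ln(2) / t_half``; e.g. the murine Avelumab half-life of 1.86 days
    gives a clearance rate of ≈ 0.3726 day⁻¹.
    """
    if not (t_half > 0):
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


def _check_positive(obj) -> None:
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be strictly "
                             f"positive and finite, got {v}")


@dataclass(frozen=True)
class BaseParams:
    """Constants of the four-compartment tumor–immune system.

    Attributes
    ----------
    r : float
        Tumor intrinsic (exponential) growth rate, day⁻¹.
    eta : float
        T-cell-mediated kill rate (mass action), mm⁻³·day⁻¹.
    delta : float
        Basal T-cell production, mm³·day⁻¹.
    lambda_T : float
        Maximum NHS-muIL12-driven T-cell stimulation rate, day⁻¹
        (CD8⁺ value 4.15 day⁻¹).
    d_T : float
        T-cell decay rate, day⁻¹.
    c1, c2 : float
        μg → effective-concentration scale factors for Avelumab and
        NHS-muIL12 respectively.
    K_A1, K_A2 : float
        Half-saturation constants of the Avelumab blockade and the
        NHS-muIL12 stimulation terms (effective-concentration units).
    K_TQ : float
        Half-saturation of T-cell suppression by the PD-1/PD-L1 complex Q.
    q0 : float
        Composite complex coefficient σ·ρ_P·ρ_L, lumped because the three
        factors only ever enter as a product.
    d_A1, d_A2 : float
        Drug clearance rates, day⁻¹ (ln 2 / half-life).
    """

    r: float = 0.17
    eta: float = 0.03
    delta: float = 1.2
    lambda_T: float = 4.15
    d_T: float = 0.35
    c1: float = 1.0e-15
    c2: float = 4.0e-15
    K_A1: float = 1.0e-13
    K_A2: float = 7.0e-14
    K_TQ: float = 3.0e4
    q0: float = 1.0
    d_A1: float = math.log(2.0) / AVELUMAB_HALF_LIFE_DAYS
    d_A2: float = math.log(2.0) / NHS_MUIL12_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        _check_positive(self)

    def replace(self, **changes) -> "BaseParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class EpsilonParams:
    """Constants of the dynamic PD-L1 expression (ε) equation.

    Defaults are the values fitted globally across the six EMT6
    treatment arms.

    Attributes
    ----------
    k_basal : float
        Maximum basal PD-L1 production rate, day⁻¹.
    K_V : float
        Half-saturation tumor volume of the production terms, mm³.
    alpha_A1 : float
        Maximum Avelumab-mediated ε suppression rate, day⁻¹.
    alpha_A2 : float
        Maximum NHS-muIL12-driven ε production rate, day⁻¹.
    d_eps : float
        Natural ε decay rate, day⁻¹.
    """

    k_basal: float = 30.5441
    K_V: float = 50.0
    alpha_A1: float = 38.2653
    alpha_A2: float = 643.6397
    d_eps: float = 0.4409

    def __post_init__(self) -> None:
        _check_positive(self)

    def replace(self, **changes) -> "EpsilonParams":
        return dataclasses.replace(self, **changes)

    @classmethod
    def mc38(cls) -> "EpsilonParams":
        """Parameters refitted to the MC38 study (400 μg Avelumab arms)."""
        return cls(k_basal=12.64, K_V=462.70, alpha_A1=3.72,
                   alpha_A2=1990.17, d_eps=0.10)


_FIELDS = {f.name for f in dataclasses.fields(BaseParams)} | \
          {f.name for f in dataclasses.fields(EpsilonParams)}


def load_params(path: Union[str, Path]):
    """Read a flat key→value config file (JSON or YAML) into parameter sets.

    Keys are exactly the field names of :class:`BaseParams` and
    :class:`EpsilonParams`; missing keys keep their defaults, unknown keys
    raise. Returns ``(BaseParams, EpsilonParams)``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a flat mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    bp_kw = {k: float(v) for k, v in raw.items()
             if k in {f.name for f in dataclasses.fields(BaseParams)}}
    ep_kw = {k: float(v) for k, v in raw.items()
             if k in {f.name for f in dataclasses.fields(EpsilonParams)}}
    return BaseParams(**bp_kw), EpsilonParams(**ep_kw)


def dump_params(bp: BaseParams, ep: EpsilonParams,
                path: Union[str, Path]) -> None:
    """Write both parameter sets to one flat JSON file."""
    payload = {**dataclasses.asdict(bp), **dataclasses.asdict(ep)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
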