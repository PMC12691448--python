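"""Treatment schedules and bolus dose application.

The experiments administer discrete injections on named days: Avelumab
intravenously on days 0, 3 and 6, NHS-muIL12 as a single subcutaneous dose
on day 0. Drug input is therefore modeled as instantaneous state jumps
(boluses) rather than continuous infusion terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

from .model import SystemState

__all__ = ["AVELUMAB", "NHS_MUIL12", "DoseEvent", "TreatmentArm",
           "standard_arms", "apply_dose", "ARM_LABELS"]

AVELUMAB = "Avelumab"
NHS_MUIL12 = "NHS-muIL12"
_DRUGS = (AVELUMAB, NHS_MUIL12)

ARM_LABELS = ("a", "b", "c", "d", "e", "f")


@dataclass(frozen=True)
class DoseEvent:
    """One bolus administration: drug, day and amount in μg."""

    day: float
    drug: str
    amount: float

    def __post_init__(self) -> None:
        if self.drug not in _DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {_DRUGS}")
        if self.day < 0:
            raise ValueError(f"dose day must be >= 0, got {self.day}")
        if not (self.amount > 0):
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class TreatmentArm:
    """Named treatment arm: an ordered (by day) list of dose events."""

    name: str
    events: Tuple[DoseEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ev = tuple(self.events)
        days = [e.day for e in ev]
        if days != sorted(days):
            ev = tuple(sorted(ev, key=lambda e: e.day))
        object.__setattr__(self, "events", ev)

    @property
    def dose_days(self) -> List[float]:
        return sorted({e.day for e in self.events})

    def total_amount(self, drug: str) -> float:
        return sum(e.amount for e in self.events if e.drug == drug)


def standard_arms(study: str = "EMT6") -> List[TreatmentArm]:
    """The six treatment arms of a study.

    EMT6: (a) isotype control; (b) NHS-muIL12 2 μg day 0;
    (c) NHS-muIL12 10 μg day 0; (d) Avelumab 200 μg days 0/3/6;
    (e) Avelumab 200 μg + NHS-muIL12 2 μg; (f) Avelumab 200 μg +
    NHS-muIL12 10 μg. MC38 uses the same layout with 400 μg Avelumab.
    """
    if study == "EMT6":
        av_dose = 200.0
    elif study == "MC38":
        av_dose = 400.0
    else:
        raise ValueError(f"unknown study {study!r}; expected 'EMT6' or 'MC38'")

    def av():
        return [DoseEvent(d, AVELUMAB, av_dose) for d in (0.0, 3.0, 6.0)]

    def nhs(amount):
        return [DoseEvent(0.0, NHS_MUIL12, amount)]

    return [
        TreatmentArm("a", ()),
        TreatmentArm("b", tuple(nhs(2.0))),
        TreatmentArm("c", tuple(nhs(10.0))),
        TreatmentArm("d", tuple(av())),
        TreatmentArm("e", tuple(av() + nhs(2.0))),
        TreatmentArm("f", tuple(av() + nhs(10.0))),
    ]


def apply_dose(state: SystemState, event: DoseEvent) -> SystemState:
    """Add the bolus amount to the targeted drug compartment."""
    if event.drug == AVELUMAB:
        return replace(state, A1=state.A1 + event.amount)
    if event.drug == NHS_MUIL12:
        return replace(state, A2=state.A2 + event.amount)
    raise ValueError(f"unknown drug {event.drug!r}")
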