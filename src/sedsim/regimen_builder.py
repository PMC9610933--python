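"""Bolus-schedule construction and regimen file handling.

Study reports give total drug doses; schedules are rebuilt with the dosing
strategies used throughout the validation:

* midazolam and fentanyl — long-acting or slow-peaking, given as a single
  undivided bolus at induction (t = 0);
* alfentanil — short-acting, split into equal boluses at 10-min intervals,
  with none given in the final 10 min of the procedure;
* propofol — split into boluses at 2–3 min intervals (longer when the
  total dose is small), with none given in the final 2 min.

Procedure timing convention: the simulation starts at t = 0, induction
lasts ``induction`` minutes (default 3), and the procedure occupies
[induction, induction + T_p].  Bolus amounts are rounded to 0.1 of the
drug's dose unit (round-half-up); any rounding remainder is carried on the
first bolus so per-drug totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pk_models import BolusDose

__all__ = ["DrugTotals", "Regimen", "build_schedule", "load_regimen", "regimen_from_dict"]

_EXPECTED_UNITS = {
    "midazolam": "mg",
    "propofol": "mg",
    "alfentanil": "ug",
    "fentanyl": "ug",
    "remifentanil": "ug",
    "morphine": "mg",
}

DEFAULT_INDUCTION = 3.0
DEFAULT_HORIZON = 60.0


@dataclass(frozen=True)
class DrugTotals:
    """Total study doses: midazolam/propofol in mg, opioid in its own unit."""

    midazolam_total: float = 0.0
    opioid_total: float = 0.0
    opioid_name: str = "fentanyl"
    propofol_total: float = 0.0

    def __post_init__(self) -> None:
        for name in ("midazolam_total", "opioid_total", "propofol_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class Regimen:
    """A complete bolus schedule plus procedure timing."""

    id: str
    boluses: tuple[BolusDose, ...]
    T_p: float
    induction: float = DEFAULT_INDUCTION
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        object.__setattr__(self, "boluses", tuple(self.boluses))
        if self.T_p <= 0:
            raise ValueError("procedure time must be positive")
        if not 0 <= self.induction < self.horizon:
            raise ValueError("induction must lie within [0, horizon)")
        for b in self.boluses:
            if not 0 <= b.time <= self.horizon:
                raise ValueError(
                    f"bolus at t={b.time} min outside the [0, {self.horizon}] min horizon"
                )

    @property
    def drugs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.boluses:
            if b.drug_name not in seen:
                seen.append(b.drug_name)
        return tuple(seen)

    def total(self, drug: str) -> float:
        return sum(b.amount for b in self.boluses if b.drug_name == drug)

    @property
    def procedure_window(self) -> tuple[float, float]:
        return (self.induction, self.induction + self.T_p)


def _round_dose(x: float, step: float = 0.1) -> float:
    # round-half-up on the 0.1-unit lattice
    import math

    return math.floor(x / step + 0.5) * step


def _equal_split(drug: str, total: float, times: list[float], round_step: float) -> list[BolusDose]:
    """Equal boluses at the given times; remainder carried on the first."""
    n = len(times)
    base = _round_dose(total / n, round_step)
    first = total - base * (n - 1)
    if first < 0:
        base = total / n
        first = base
    amounts = [first] + [base] * (n - 1)
    return [BolusDose(drug, a, t) for a, t in zip(amounts, times)]


def build_schedule(
    totals: DrugTotals,
    T_p: float,
    induction: float = DEFAULT_INDUCTION,
    horizon: float = DEFAULT_HORIZON,
    regimen_id: str = "built",
    propofol_max_bolus: float = 30.0,
    propofol_interval: float = 2.0,
    propofol_small_interval: float = 3.0,
    propofol_small_n: int = 3,
) -> Regimen:
    """Construct a rule-based bolus schedule from total doses.

    Propofol is divided into ``ceil(total / propofol_max_bolus)`` equal
    boluses spaced ``propofol_interval`` min apart (``propofol_small_interval``
    when at most ``propofol_small_n`` boluses are needed), the last no later
    than ``induction + T_p - 2`` min.  Alfentanil boluses sit at 0, 10, 20, …
    min, the last no later than ``induction + T_p - 10`` min.  Raises when a
    required bolus cannot be placed under these constraints.
    """
    import math

    if T_p <= 0:
        raise ValueError("procedure time must be positive")
    boluses: list[BolusDose] = []
    if totals.midazolam_total > 0:
        boluses.append(BolusDose("midazolam", totals.midazolam_total, 0.0))
    if totals.opioid_total > 0:
        opioid = totals.opioid_name
        if opioid not in _EXPECTED_UNITS:
            raise ValueError(f"unknown opioid {opioid!r}")
        if opioid == "alfentanil":
            latest = induction + T_p - 10.0
            if latest < 0:
                raise ValueError(
                    f"procedure too short ({T_p} min) to place any alfentanil bolus"
                )
            times = [float(t) for t in range(0, int(math.floor(latest)) + 1, 10)]
            boluses.extend(_equal_split("alfentanil", totals.opioid_total, times, 1.0))
        else:
            boluses.append(BolusDose(opioid, totals.opioid_total, 0.0))
    if totals.propofol_total > 0:
        latest = induction + T_p - 2.0
        if latest < 0:
            raise ValueError(f"procedure too short ({T_p} min) to place any propofol bolus")
        n = max(1, math.ceil(totals.propofol_total / propofol_max_bolus))
        interval = propofol_small_interval if n <= propofol_small_n else propofol_interval
        if (n - 1) * interval > latest:
            interval = propofol_interval
        if (n - 1) * interval > latest:
            # short procedure: fewer, larger boluses at the minimum spacing
            n = int(math.floor(latest / propofol_interval)) + 1
        times = [i * interval for i in range(n)]
        boluses.extend(_equal_split("propofol", totals.propofol_total, times, 0.1))
    return Regimen(id=regimen_id, boluses=tuple(boluses), T_p=T_p, induction=induction, horizon=horizon)


def regimen_from_dict(data: dict) -> Regimen:
    """Validate a plain-dict regimen definition (the YAML schema)."""
    for key in ("id", "T_p", "boluses"):
        if key not in data:
            raise ValueError(f"regimen definition missing required field {key!r}")
    boluses = []
    for i, b in enumerate(data["boluses"]):
        for key in ("drug", "amount", "unit", "time"):
            if key not in b:
                raise ValueError(f"bolus #{i} missing required field {key!r}")
        drug = b["drug"]
        if drug not in _EXPECTED_UNITS:
            raise ValueError(f"unknown drug {drug!r} in bolus #{i}")
        if b["unit"] != _EXPECTED_UNITS[drug]:
            raise ValueError(
                f"bolus #{i}: {drug} must be dosed in {_EXPECTED_UNITS[drug]!r}, got {b['unit']!r}"
            )
        boluses.append(BolusDose(drug, float(b["amount"]), float(b["time"])))
    return Regimen(
        id=str(data["id"]),
        boluses=tuple(boluses),
        T_p=float(data["T_p"]),
        induction=float(data.get("induction", DEFAULT_INDUCTION)),
        horizon=float(data.get("horizon", DEFAULT_HORIZON)),
    )


def load_regimen(path: str | Path) -> Regimen:
    """Load and validate a single-regimen YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: regimen file must contain a mapping")
    return regimen_from_dict(data)
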