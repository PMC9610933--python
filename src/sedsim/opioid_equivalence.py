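"""Opioid potency conversion onto the alfentanil concentration axis.

The response surface takes its opioid input as an alfentanil effect-site
concentration (ng/mL).  Other opioids are mapped linearly onto that axis by
a relative-potency factor: alfentanil-equivalent Ce per unit of the opioid's
own Ce.  Default factors are derived from published effect-site C50 ratios
(minimum effective analgesic concentrations); alfentanil is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["PotencyTable", "alfentanil_equivalent", "SUPPORTED_OPIOIDS"]

SUPPORTED_OPIOIDS = ("alfentanil", "fentanyl", "remifentanil", "morphine")

#: default alfentanil-equivalent ng/mL per ng/mL of opioid, from C50 ratios
#: (alfentanil ~75, fentanyl ~1.2, remifentanil ~1.25, morphine ~15 ng/mL)
_DEFAULT_FACTORS: dict[str, float] = {
    "alfentanil": 1.0,
    "fentanyl": 62.5,
    "remifentanil": 60.0,
    "morphine": 5.0,
}

_DEFAULT_UNITS: dict[str, str] = {name: "ng/mL" for name in SUPPORTED_OPIOIDS}


@dataclass(frozen=True)
class PotencyTable:
    """Per-opioid linear scale factors onto alfentanil-equivalent Ce."""

    factors: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_FACTORS))
    ce_units: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_UNITS))

    def __post_init__(self) -> None:
        if "alfentanil" not in self.factors or self.factors["alfentanil"] != 1.0:
            raise ValueError("potency table must define alfentanil with factor 1.0")
        for drug, factor in self.factors.items():
            if factor <= 0:
                raise ValueError(f"potency factor for {drug!r} must be positive")
            if drug not in self.ce_units:
                raise ValueError(f"missing Ce unit declaration for {drug!r}")


def alfentanil_equivalent(ce, drug: str, table: PotencyTable | None = None):
    """Convert an opioid effect-site concentration to alfentanil equivalents.

    Pure linear scaling: homogeneous, additive, and therefore exchangeable
    with superposition of concentration trajectories.  Accepts scalars or
    arrays; alfentanil passes through unchanged.
    """
    if table is None:
        table = PotencyTable()
    if drug not in table.factors:
        supported = ", ".join(sorted(table.factors))
        raise ValueError(f"unknown opioid {drug!r}; supported: {supported}")
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValueError("effect-site concentration must be nonnegative")
    out = table.factors[drug] * ce_arr
    return float(out) if np.isscalar(ce) or ce_arr.ndim == 0 else out
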