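"""Synthetic inputs with known ground truth for end-to-end testing.

Two generators are provided: random-but-rule-conforming bolus regimens
(seeded, bytewise reproducible), and planted piecewise-linear probability
trajectories whose threshold-crossing times are known in closed form, so
recovery detection and deep-sedation measurement can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pd_surface import ProbabilityTrajectory
from .regimen_builder import DrugTotals, Regimen, build_schedule

__all__ = ["SyntheticSpec", "synthetic_regimen", "planted_triangle", "triangle_crossing"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Dose/procedure ranges for random regimen generation."""

    seed: int = 0
    midazolam_range: tuple[float, float] = (0.0, 5.0)
    opioid_range: tuple[float, float] = (0.0, 100.0)
    opioid_name: str = "fentanyl"
    propofol_range: tuple[float, float] = (0.0, 350.0)
    T_p_range: tuple[float, float] = (8.0, 30.0)

    def __post_init__(self) -> None:
        for name in ("midazolam_range", "opioid_range", "propofol_range", "T_p_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")
        if self.T_p_range[0] <= 0:
            raise ValueError("procedure time range must be positive")


def synthetic_regimen(spec: SyntheticSpec, regimen_id: str = "synthetic") -> Regimen:
    """A reproducible random regimen obeying the bolus-placement rules."""
    rng = np.random.default_rng(spec.seed)
    totals = DrugTotals(
        midazolam_total=round(rng.uniform(*spec.midazolam_range), 1),
        opioid_total=round(rng.uniform(*spec.opioid_range), 1),
        opioid_name=spec.opioid_name,
        propofol_total=round(rng.uniform(*spec.propofol_range), 1),
    )
    T_p = round(rng.uniform(*spec.T_p_range), 1)
    return build_schedule(totals, T_p, regimen_id=regimen_id)


def planted_triangle(
    peak_time: float = 10.0,
    peak_p: float = 0.8,
    end_time: float = 20.0,
    grid_step: float = 0.01,
) -> ProbabilityTrajectory:
    """A triangular P(LOR) course: 0 at t=0, ``peak_p`` at ``peak_time``, 0 at ``end_time``."""
    grid = np.arange(0.0, end_time + grid_step / 2, grid_step)
    up = peak_p * grid / peak_time
    down = peak_p * (end_time - grid) / (end_time - peak_time)
    p = np.clip(np.minimum(up, down), 0.0, 1.0)
    return ProbabilityTrajectory(grid=grid, p_lor=p)


def triangle_crossing(
    threshold: float,
    peak_time: float = 10.0,
    peak_p: float = 0.8,
    end_time: float = 20.0,
) -> float:
    """Closed-form descending-limb crossing time of the planted triangle."""
    if not 0 < threshold < peak_p:
        raise ValueError("threshold must lie strictly between 0 and the peak")
    return end_time - threshold * (end_time - peak_time) / peak_p
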