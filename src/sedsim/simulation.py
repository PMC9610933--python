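"""Full sedation-course simulation and its two clinical summary outputs.

A :class:`SedationCourse` holds, on one time grid over [0, horizon]:
per-drug effect-site trajectories, the alfentanil-equivalent opioid level,
and the probability of loss of response P(MOAA/S < 2).  From the course two
quantities are extracted:

* the model-predicted recovery time ``T_rm`` — the first time after the
  probability peak at which P(LOR) falls below the recovery threshold
  (default 5%), measured from simulation start;
* the intraprocedural deep-sedation ratio — the fraction of the procedure
  window during which P(LOR) strictly exceeds the deep-sedation threshold
  (default 50%).

Both crossings are refined by linear interpolation between grid points, so
results are stable to well below the grid step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .opioid_equivalence import PotencyTable, alfentanil_equivalent
from .pd_surface import ProbabilityTrajectory, SurfaceParameters, probability_course
from .pk_models import ConcentrationTrajectory, PKParameters, effect_site_trajectory
from .regimen_builder import Regimen

__all__ = [
    "SimulationSettings",
    "SedationCourse",
    "NoSedationEvent",
    "NoRecoveryWithinHorizon",
    "simulate_course",
    "predicted_recovery_time",
    "deep_sedation_ratio",
    "write_course_csv",
]


class NoSedationEvent(ValueError):
    """P(LOR) never exceeds the recovery threshold: no sedation to recover from."""


class NoRecoveryWithinHorizon(ValueError):
    """P(LOR) does not fall below the recovery threshold before the horizon."""


@dataclass(frozen=True)
class SimulationSettings:
    """Timing grid and probability cutoffs for a simulation run."""

    induction: float = 3.0
    horizon: float = 60.0
    grid_step: float = 0.01
    recovery_threshold: float = 0.05
    deep_threshold: float = 0.50

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not 0 < self.recovery_threshold < self.deep_threshold < 1:
            raise ValueError("need 0 < recovery_threshold < deep_threshold < 1")
        if not 0 <= self.induction < self.horizon:
            raise ValueError("induction must lie within [0, horizon)")

    def grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.grid_step))
        return np.linspace(0.0, self.horizon, n + 1)


@dataclass(frozen=True)
class SedationCourse:
    """Simulated time course of one regimen."""

    regimen_id: str
    grid: np.ndarray
    trajectories: Mapping[str, ConcentrationTrajectory]
    ce_alf_equiv: np.ndarray
    p_lor: ProbabilityTrajectory
    procedure_window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.procedure_window
        if not (self.grid[0] <= lo < hi <= self.grid[-1]):
            raise ValueError("procedure window must lie within the simulated grid span")


def simulate_course(
    regimen: Regimen,
    pk_registry: Mapping[str, PKParameters],
    table: PotencyTable,
    sp: SurfaceParameters,
    settings: SimulationSettings | None = None,
) -> SedationCourse:
    """Compose PK superposition, opioid conversion, and the response surface.

    Deterministic given its inputs.  Raises ``KeyError`` naming the drug when
    the regimen uses a drug absent from the PK registry.
    """
    if settings is None:
        settings = SimulationSettings(induction=regimen.induction, horizon=regimen.horizon)
    grid = settings.grid()
    trajs: dict[str, ConcentrationTrajectory] = {}
    for drug in regimen.drugs:
        if drug not in pk_registry:
            raise KeyError(f"no PK parameters configured for {drug!r}")
        doses = [b for b in regimen.boluses if b.drug_name == drug]
        trajs[drug] = effect_site_trajectory(doses, pk_registry[drug], grid)
    ce_alf_eq = np.zeros_like(grid)
    for drug, traj in trajs.items():
        if drug in table.factors:
            ce_alf_eq = alfentanil_equivalent(traj.ce, drug, table)
    if trajs:
        p = probability_course(trajs, table, sp)
    else:
        p = ProbabilityTrajectory(grid=grid, p_lor=np.zeros_like(grid))
    window = (regimen.induction, min(regimen.induction + regimen.T_p, settings.horizon))
    return SedationCourse(
        regimen_id=regimen.id,
        grid=grid,
        trajectories=trajs,
        ce_alf_equiv=ce_alf_eq,
        p_lor=p,
        procedure_window=window,
    )


def predicted_recovery_time(
    course: SedationCourse | ProbabilityTrajectory,
    threshold: float = 0.05,
) -> float:
    """First post-peak time at which P(LOR) drops below ``threshold``.

    The search starts at the global maximum of the probability trajectory
    (recovery is a descending-limb event; the sub-threshold span before
    induction does not count).  The crossing is refined by linear
    interpolation.  A boundary value p == threshold counts as recovered.
    """
    traj = course.p_lor if isinstance(course, SedationCourse) else course
    t = traj.grid
    p = traj.p_lor
    if np.max(p) <= threshold:
        raise NoSedationEvent(
            f"P(LOR) never exceeds the {threshold:.0%} recovery threshold"
        )
    i_peak = int(np.argmax(p))
    below = np.nonzero(p[i_peak:] <= threshold)[0]
    if below.size == 0:
        raise NoRecoveryWithinHorizon(
            f"P(LOR) stays above {threshold:.0%} through the {t[-1]:.0f}-min horizon"
        )
    j = i_peak + below[0]
    if p[j] == threshold or j == 0:
        return float(t[j])
    # linear interpolation on the segment [j-1, j] straddling the threshold
    t0, t1 = t[j - 1], t[j]
    p0, p1 = p[j - 1], p[j]
    return float(t0 + (p0 - threshold) / (p0 - p1) * (t1 - t0))


def deep_sedation_ratio(
    course: SedationCourse,
    threshold: float = 0.50,
) -> float:
    """Fraction of the procedure window with P(LOR) strictly above ``threshold``.

    The probability trajectory is treated as piecewise linear; the measure of
    the super-threshold set is computed exactly on that interpolant, so the
    result is grid-robust.  Boundary p == threshold counts as not deep.
    """
    lo, hi = course.procedure_window
    if hi <= lo:
        raise ValueError("empty procedure window")
    t = course.p_lor.grid
    p = course.p_lor.p_lor
    # restrict to the window, with exact interpolated endpoints
    inner = (t > lo) & (t < hi)
    tw = np.concatenate(([lo], t[inner], [hi]))
    pw = np.concatenate(([np.interp(lo, t, p)], p[inner], [np.interp(hi, t, p)]))
    measure = 0.0
    for k in range(tw.size - 1):
        dt = tw[k + 1] - tw[k]
        a, b = pw[k] - threshold, pw[k + 1] - threshold
        if a > 0 and b > 0:
            measure += dt
        elif a > 0 >= b:
            measure += dt * a / (a - b)
        elif a <= 0 < b:
            measure += dt * b / (b - a)
    return float(measure / (hi - lo))


def write_course_csv(course: SedationCourse, path: str | Path) -> None:
    """Write the course as CSV: t_min, per-drug Ce, alfentanil equivalents, p_lor."""
    grid = course.grid
    zero = np.zeros_like(grid)
    get = lambda d: course.trajectories[d].ce if d in course.trajectories else zero
    opioids = [d for d in course.trajectories if d not in ("midazolam", "propofol")]
    ce_op = get(opioids[0]) if opioids else zero
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_min", "ce_mid", "ce_opioid", "ce_alf_equiv", "ce_prop", "p_lor"])
        for row in zip(grid, get("midazolam"), ce_op, course.ce_alf_equiv, get("propofol"), course.p_lor.p_lor):
            writer.writerow([f"{v:.6g}" for v in row])
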