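"""Three-drug response surface for the probability of loss of response.

The sedation endpoint is loss of response (LOR), MOAA/S < 2.  Its
probability is modelled with a Greco-family interaction surface: each
drug's effect-site concentration is normalised by its potency C50, the
normalised drives combine additively plus pairwise and triple interaction
terms, and a Hill function maps the total drive to probability:

    U = Cm/C50m + Ca/C50a + Cp/C50p
        + beta_ma (Cm/C50m)(Ca/C50a) + beta_mp (Cm/C50m)(Cp/C50p)
        + beta_ap (Ca/C50a)(Cp/C50p) + beta_map (Cm/C50m)(Ca/C50a)(Cp/C50p)

    P(LOR) = U^gamma / (1 + U^gamma)

Positive betas encode synergy; all betas zero gives pure additivity.  The
opioid axis is expressed in alfentanil-equivalent Ce (see
:mod:`sedsim.opioid_equivalence`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .opioid_equivalence import PotencyTable, alfentanil_equivalent
from .pk_models import ConcentrationTrajectory

__all__ = [
    "SurfaceParameters",
    "ProbabilityTrajectory",
    "lor_probability",
    "probability_course",
]


@dataclass(frozen=True)
class SurfaceParameters:
    """Potencies (C50, in each drug's Ce unit), Hill steepness, interactions."""

    C50_mid: float
    C50_alf: float
    C50_prop: float
    gamma: float
    beta_ma: float = 0.0
    beta_mp: float = 0.0
    beta_ap: float = 0.0
    beta_map: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C50_mid", "C50_alf", "C50_prop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for name in ("beta_ma", "beta_mp", "beta_ap", "beta_map"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ProbabilityTrajectory:
    """P(MOAA/S < 2) sampled on a time grid."""

    grid: np.ndarray
    p_lor: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.p_lor, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "p_lor", p)
        if p.shape != grid.shape:
            raise ValueError("grid and p_lor must have equal length")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def lor_probability(ce_mid, ce_alf_eq, ce_prop, sp: SurfaceParameters):
    """Probability of loss of response given the three effect-site levels.

    ``ce_alf_eq`` must already be in alfentanil equivalents.  Accepts
    scalars or broadcastable arrays; returns values in [0, 1].
    """
    cm = np.asarray(ce_mid, dtype=float)
    ca = np.asarray(ce_alf_eq, dtype=float)
    cp = np.asarray(ce_prop, dtype=float)
    if np.any(cm < 0) or np.any(ca < 0) or np.any(cp < 0):
        raise ValueError("effect-site concentrations must be nonnegative")
    um = cm / sp.C50_mid
    ua = ca / sp.C50_alf
    up = cp / sp.C50_prop
    U = (
        um
        + ua
        + up
        + sp.beta_ma * um * ua
        + sp.beta_mp * um * up
        + sp.beta_ap * ua * up
        + sp.beta_map * um * ua * up
    )
    Ug = np.power(U, sp.gamma)
    with np.errstate(over="ignore"):
        p = np.where(np.isinf(Ug), 1.0, Ug / (1.0 + Ug))
    scalar = all(np.isscalar(x) or np.asarray(x).ndim == 0 for x in (ce_mid, ce_alf_eq, ce_prop))
    return float(p) if scalar else p


def probability_course(
    trajs: Mapping[str, ConcentrationTrajectory],
    table: PotencyTable,
    sp: SurfaceParameters,
) -> ProbabilityTrajectory:
    """Pointwise surface evaluation over per-drug trajectories on one grid.

    ``trajs`` maps drug names to trajectories; a missing drug contributes a
    zero trajectory.  At most one opioid may be present; it is converted to
    alfentanil equivalents before the surface.
    """
    if not trajs:
        raise ValueError("at least one trajectory is required")
    grids = [t.grid for t in trajs.values()]
    grid = grids[0]
    for g in grids[1:]:
        if g.shape != grid.shape or not np.allclose(g, grid):
            raise ValueError("all trajectories must share one time grid")
    zero = np.zeros_like(grid)
    ce_mid = zero
    ce_prop = zero
    ce_alf_eq = zero
    opioid_seen = None
    for drug, traj in trajs.items():
        if drug == "midazolam":
            ce_mid = traj.ce
        elif drug == "propofol":
            ce_prop = traj.ce
        elif drug in table.factors:
            if opioid_seen is not None:
                raise ValueError(f"multiple opioids given: {opioid_seen}, {drug}")
            opioid_seen = drug
            ce_alf_eq = alfentanil_equivalent(traj.ce, drug, table)
        else:
            raise ValueError(f"drug {drug!r} is not midazolam, propofol, or a known opioid")
    p = lor_probability(ce_mid, ce_alf_eq, ce_prop, sp)
    return ProbabilityTrajectory(grid=grid, p_lor=p)
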