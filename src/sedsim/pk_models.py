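"""Analytic effect-site pharmacokinetics for IV bolus dosing.

Drug disposition is described by a mammillary two- or three-compartment
model parameterised by micro rate constants (``k10``, ``k12``, ``k21``,
``k13``, ``k31``, all 1/min) and a central volume ``V1`` (L).  The effect
site is a negligible-volume compartment linked to plasma by a first-order
equilibration constant ``ke0``:

    dCe/dt = ke0 * (Cp(t) - Ce(t))

For a unit IV bolus the plasma concentration is a sum of exponentials,
``Cp(t) = (1/V1) * sum_i w_i * exp(mu_i t)`` with ``mu_i`` the (negative)
eigenvalues of the disposition matrix, so the effect-site concentration
has the closed form

    Ce(t) = (ke0/V1) * sum_i w_i * (exp(mu_i t) - exp(-ke0 t)) / (ke0 + mu_i)

Arbitrary bolus schedules follow by linear superposition of time-shifted
unit responses.  Concentrations carry the units implied by ``dose_unit``
per litre (mg -> ug/mL, ug -> ng/mL); no hidden unit scaling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PKParameters",
    "BolusDose",
    "ConcentrationTrajectory",
    "unit_bolus_response",
    "effect_site_trajectory",
    "time_to_peak_effect",
]

# relative perturbation applied to ke0 when it collides with a disposition
# eigenvalue (the closed form has a removable singularity there)
_DEGENERACY_EPS = 1e-9


@dataclass(frozen=True)
class PKParameters:
    """Micro-rate-constant parameter set for one drug.

    ``k13`` and ``k31`` must both be zero when ``n_compartments`` is 2.
    ``ce_unit`` is declarative: it must equal ``dose_unit`` per litre
    (mg -> "ug/mL", ug -> "ng/mL") because the model divides dose by V1.
    """

    drug_name: str
    n_compartments: int
    V1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float
    ke0: float
    dose_unit: str = "mg"
    ce_unit: str = "ug/mL"

    def __post_init__(self) -> None:
        if self.n_compartments not in (2, 3):
            raise ValueError("n_compartments must be 2 or 3")
        if self.V1 <= 0:
            raise ValueError("V1 must be positive")
        if self.ke0 <= 0:
            raise ValueError("ke0 must be positive")
        for name in ("k10", "k12", "k21"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_compartments == 2:
            if self.k13 != 0.0 or self.k31 != 0.0:
                raise ValueError("k13 and k31 must be zero for a 2-compartment model")
        else:
            if self.k13 <= 0 or self.k31 <= 0:
                raise ValueError("k13 and k31 must be positive for a 3-compartment model")


@dataclass(frozen=True)
class BolusDose:
    """A single IV bolus: ``amount`` in the drug's dose unit at ``time`` minutes."""

    drug_name: str
    amount: float
    time: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("bolus amount must be nonnegative")
        if self.time < 0:
            raise ValueError("bolus time must be nonnegative")


@dataclass(frozen=True)
class ConcentrationTrajectory:
    """Effect-site concentration sampled on a strictly increasing time grid."""

    drug_name: str
    grid: np.ndarray
    ce: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        ce = np.asarray(self.ce, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "ce", ce)
        if grid.ndim != 1 or ce.shape != grid.shape:
            raise ValueError("grid and ce must be 1-D arrays of equal length")
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(ce < 0):
            raise ValueError("effect-site concentrations must be nonnegative")


def _disposition_matrix(pk: PKParameters) -> np.ndarray:
    if pk.n_compartments == 2:
        return np.array(
            [
                [-(pk.k10 + pk.k12), pk.k21],
                [pk.k12, -pk.k21],
            ]
        )
    return np.array(
        [
            [-(pk.k10 + pk.k12 + pk.k13), pk.k21, pk.k31],
            [pk.k12, -pk.k21, 0.0],
            [pk.k13, 0.0, -pk.k31],
        ]
    )


@lru_cache(maxsize=128)
def _exponential_terms(pk: PKParameters) -> tuple[np.ndarray, np.ndarray, float]:
    """Eigen-decompose the disposition matrix for a unit central bolus.

    Returns ``(mu, w, ke0)`` with ``Cp(t) = (1/V1) sum w_i exp(mu_i t)`` and a
    ke0 nudged off any eigenvalue collision so the closed form stays finite.
    """
    M = _disposition_matrix(pk)
    mu, vecs = np.linalg.eig(M)
    # mammillary models with positive rates have real, distinct eigenvalues
    if np.max(np.abs(mu.imag)) > 1e-10 * np.max(np.abs(mu.real)):
        raise ValueError(f"unexpected complex disposition eigenvalues for {pk.drug_name}")
    mu = mu.real
    vecs = vecs.real
    a0 = np.zeros(pk.n_compartments)
    a0[0] = 1.0
    coeff = np.linalg.solve(vecs, a0)
    w = vecs[0, :] * coeff
    ke0 = pk.ke0
    while np.any(np.abs(ke0 + mu) < _DEGENERACY_EPS * ke0):
        ke0 *= 1.0 + _DEGENERACY_EPS
    return mu, w, ke0


def unit_bolus_response(pk: PKParameters, t: float | Sequence[float] | np.ndarray):
    """Effect-site concentration at time ``t`` (min) after a unit bolus at t=0.

    Returns a scalar for scalar input, an array for array input.  ``t`` must
    be nonnegative.  Ce(0) = 0 and Ce decays to 0 as t grows.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    mu, w, ke0 = _exponential_terms(pk)
    tt = t_arr[..., np.newaxis]
    terms = w * (np.exp(mu * tt) - np.exp(-ke0 * tt)) / (ke0 + mu)
    ce = (ke0 / pk.V1) * terms.sum(axis=-1)
    ce = np.maximum(ce, 0.0)  # clip roundoff-level negatives
    return float(ce) if np.isscalar(t) or t_arr.ndim == 0 else ce


def effect_site_trajectory(
    doses: Sequence[BolusDose],
    pk: PKParameters,
    grid: Sequence[float] | np.ndarray,
) -> ConcentrationTrajectory:
    """Superpose shifted unit-bolus responses over a bolus schedule.

    ``ce(t) = sum_i amount_i * unit_bolus_response(pk, t - time_i)`` for
    ``t >= time_i``; doses not yet given contribute nothing.
    """
    grid_arr = np.asarray(grid, dtype=float)
    ce = np.zeros_like(grid_arr)
    for dose in doses:
        if dose.drug_name != pk.drug_name:
            raise ValueError(
                f"dose for {dose.drug_name!r} cannot use {pk.drug_name!r} parameters"
            )
        mask = grid_arr >= dose.time
        if np.any(mask):
            ce[mask] += dose.amount * unit_bolus_response(pk, grid_arr[mask] - dose.time)
    return ConcentrationTrajectory(drug_name=pk.drug_name, grid=grid_arr, ce=ce)


def time_to_peak_effect(pk: PKParameters, search_horizon: float = 120.0) -> float:
    """Time (min) at which the unit-bolus effect-site concentration peaks.

    Located by a coarse grid scan followed by bounded scalar maximization;
    resolution is well below 1e-3 min.
    """
    coarse = np.linspace(1e-4, search_horizon, 4096)
    ce = unit_bolus_response(pk, coarse)
    i = int(np.argmax(ce))
    lo = coarse[max(i - 1, 0)]
    hi = coarse[min(i + 1, coarse.size - 1)]
    res = minimize_scalar(
        lambda t: -unit_bolus_response(pk, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)
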