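"""Validation bookkeeping: model predictions versus published study outcomes.

Each clinical study contributes one regimen with a reported mean procedure
time ``T_p`` and mean recovery time ``T_rs`` (measured from procedure end).
The observed recovery time measured from simulation start is

    T_ro = induction + T_p + T_rs
    T_ro range = T_ro ± T_rs SD

A negative stored SD encodes a one-sided lower range [T_ro − |SD|, T_ro],
used for studies that reported only the time window within which the last
patients recovered.

Recovery accuracy is assessed two ways: individually (T_rm inside the T_ro
range) and against the pooled criterion (|T_rm − T_ro| within half of the
across-study mean T_rs).  Sedation-depth accuracy compares the dominating
predicted depth — deep when the intraprocedural deep-sedation ratio exceeds
0.5 — with the study's stated target; studies that reported no sedation
score are not evaluable.  The overall accuracy pools both endpoints:
100 × (recovery hits + depth hits) / (regimens + evaluable regimens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "StudyRecord",
    "ValidationResult",
    "ValidationReport",
    "observed_recovery_time",
    "pooled_accuracy_margin",
    "assess_regimen",
    "validate_all",
    "round_half_up",
]

_TARGETS = ("moderate", "deep", "not_reported")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in the reported tables."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class StudyRecord:
    """One study regimen's reported outcomes.

    ``T_rs_sd < 0`` means a one-sided lower range of width ``|T_rs_sd|``
    (the study reported only an upper-bounded recovery window).
    """

    regimen_id: str
    source: str
    sedation_target: str
    recovery_scale: str
    T_p: float
    T_rs: float
    T_rs_sd: float
    procedure: str = ""

    def __post_init__(self) -> None:
        if self.T_p <= 0:
            raise ValueError("T_p must be positive")
        if self.T_rs < 0:
            raise ValueError("T_rs must be nonnegative")
        if self.sedation_target not in _TARGETS:
            raise ValueError(f"sedation_target must be one of {_TARGETS}")


@dataclass(frozen=True)
class ValidationResult:
    """Per-regimen comparison of model prediction with the study outcome."""

    regimen_id: str
    T_rm: float
    T_ro: float
    T_ro_range: tuple[float, float]
    abs_error: float
    pct_error: float
    within_range: bool
    within_margin: bool
    deep_ratio: float | None
    predicted_depth: str | None
    depth_agrees: bool | None


@dataclass(frozen=True)
class ValidationReport:
    """Aggregate bookkeeping across all regimens."""

    results: tuple[ValidationResult, ...]
    pooled_mean_Trs: float
    half_margin: float
    n_recovery_accurate_range: int
    n_recovery_accurate_margin: int
    n_depth_agree: int
    n_depth_evaluable: int
    overall_accuracy: float


def observed_recovery_time(
    rec: StudyRecord, induction: float = 3.0
) -> tuple[float, tuple[float, float]]:
    """Observed recovery time and its range, from simulation start."""
    T_ro = induction + rec.T_p + rec.T_rs
    if rec.T_rs_sd < 0:
        rng = (T_ro - abs(rec.T_rs_sd), T_ro)
    else:
        rng = (T_ro - rec.T_rs_sd, T_ro + rec.T_rs_sd)
    return T_ro, rng


def pooled_accuracy_margin(records: Sequence[StudyRecord]) -> tuple[float, float]:
    """Across-study mean T_rs and its half, the pooled accuracy margin."""
    if not records:
        raise ValueError("at least one study record is required")
    mean = sum(r.T_rs for r in records) / len(records)
    return mean, mean / 2.0


def assess_regimen(
    rec: StudyRecord,
    T_rm: float,
    deep_ratio: float | None,
    half_margin: float,
    induction: float = 3.0,
) -> ValidationResult:
    """Build the full per-regimen comparison.

    Comparisons use unrounded values; rounding is a presentation concern.
    A deep ratio of exactly 0.5 classifies as moderate (deep requires the
    ratio to exceed one half).
    """
    T_ro, rng = observed_recovery_time(rec, induction)
    abs_error = T_rm - T_ro
    pct_error = abs_error / T_ro
    within_range = rng[0] <= T_rm <= rng[1]
    within_margin = abs(abs_error) <= half_margin
    if deep_ratio is None:
        predicted_depth = None
        depth_agrees = None
    else:
        predicted_depth = "deep" if deep_ratio > 0.5 else "moderate"
        if rec.sedation_target == "not_reported":
            depth_agrees = None
        else:
            depth_agrees = predicted_depth == rec.sedation_target
    return ValidationResult(
        regimen_id=rec.regimen_id,
        T_rm=T_rm,
        T_ro=T_ro,
        T_ro_range=rng,
        abs_error=abs_error,
        pct_error=pct_error,
        within_range=within_range,
        within_margin=within_margin,
        deep_ratio=deep_ratio,
        predicted_depth=predicted_depth,
        depth_agrees=depth_agrees,
    )


def validate_all(
    records: Sequence[StudyRecord],
    predictions: Mapping[str, tuple[float, float | None]],
    induction: float = 3.0,
) -> ValidationReport:
    """Aggregate per-regimen assessments into the summary report.

    ``predictions`` maps regimen id to ``(T_rm, deep_ratio-or-None)``.  Two
    usage modes share this entry point: predictions computed by running
    :func:`sedsim.simulation.simulate_course` on each regimen, or reference
    predictions taken from a published results table so the bookkeeping can
    be reproduced independently of any model configuration.
    """
    ids = [r.regimen_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate regimen ids in study records")
    missing = [i for i in ids if i not in predictions]
    if missing:
        raise ValueError(f"missing predictions for regimens: {missing}")
    mean_Trs, half_margin = pooled_accuracy_margin(records)
    results = tuple(
        assess_regimen(rec, *predictions[rec.regimen_id], half_margin, induction)
        for rec in records
    )
    n_range = sum(r.within_range for r in results)
    n_margin = sum(r.within_margin for r in results)
    n_eval = sum(r.depth_agrees is not None for r in results)
    n_agree = sum(bool(r.depth_agrees) for r in results)
    overall = 100.0 * (n_range + n_agree) / (len(results) + n_eval)
    return ValidationReport(
        results=results,
        pooled_mean_Trs=mean_Trs,
        half_margin=half_margin,
        n_recovery_accurate_range=n_range,
        n_recovery_accurate_margin=n_margin,
        n_depth_agree=n_agree,
        n_depth_evaluable=n_eval,
        overall_accuracy=overall,
    )
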