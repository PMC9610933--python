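"""Packaged validation fixtures: the nine study regimens and their outcomes.

The fixture set bundles, as plain CSV/YAML inside the package:

* the nine study outcome records (procedure time, reported recovery time
  and its SD, sedation target) from the six source endoscopy studies;
* the nine simulated bolus schedules exactly as run in the validation;
* the per-regimen reference outcomes (predicted recovery time T_rm,
  observed recovery time T_ro with its range, intraprocedural
  deep-sedation ratio) for reference-mode bookkeeping;
* the reference patient (female, 170 cm, 65 kg, ASA 2).

SHA-256 checksums guard the data files against accidental edits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .regimen_builder import Regimen, regimen_from_dict
from .validation import StudyRecord

__all__ = ["FixtureSet", "ReferenceOutcome", "load_fixtures"]

_CHECKSUMS = {
    "study_records.csv": "7f64e1b3b480c819ef08ab4fa492e348fcb88779fd5b7546fac1a3ce73334760",
    "regimens.yaml": "fbc369008de40f89cf23912cc20dd5ad589a5c4f4ff79785914031055ed99011",
    "reference_outcomes.csv": "590682bdf83b871a1080793ba73ec8082cadc2c2e58815e5ab7f2e182c55e5e7",
}


@dataclass(frozen=True)
class ReferenceOutcome:
    """One regimen's published simulation outcome (reference mode input)."""

    regimen_id: str
    T_rm: float
    T_ro: float
    T_ro_range: tuple[float, float]
    deep_ratio: float | None


@dataclass(frozen=True)
class FixtureSet:
    """The complete packaged validation inputs."""

    study_records: tuple[StudyRecord, ...]
    regimens: tuple[Regimen, ...]
    reference_outcomes: tuple[ReferenceOutcome, ...]
    reference_patient: Mapping[str, object]

    def record(self, regimen_id: str) -> StudyRecord:
        return next(r for r in self.study_records if r.regimen_id == regimen_id)

    def regimen(self, regimen_id: str) -> Regimen:
        return next(r for r in self.regimens if r.id == regimen_id)

    def reference(self, regimen_id: str) -> ReferenceOutcome:
        return next(r for r in self.reference_outcomes if r.regimen_id == regimen_id)


def _read(name: str) -> bytes:
    raw = resources.files("sedsim.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(
            f"fixture file {name} has been modified (sha256 {digest[:12]}… does not match)"
        )
    return raw


def load_fixtures(verify: bool = True) -> FixtureSet:
    """Load and validate the packaged fixture set.

    ``verify=False`` skips the checksum guard (useful when regenerating
    the data files).
    """
    import io

    def read(name: str) -> bytes:
        if verify:
            return _read(name)
        return resources.files("sedsim.data").joinpath(name).read_bytes()

    records_df = pd.read_csv(io.BytesIO(read("study_records.csv")), dtype={"regimen_id": str})
    records = tuple(
        StudyRecord(
            regimen_id=row.regimen_id,
            source=row.source,
            sedation_target=row.sedation_target,
            recovery_scale=row.recovery_scale,
            T_p=float(row.T_p),
            T_rs=float(row.T_rs),
            T_rs_sd=float(row.T_rs_sd),
            procedure=row.procedure,
        )
        for row in records_df.itertuples()
    )

    reg_data = yaml.safe_load(read("regimens.yaml"))
    regimens = tuple(regimen_from_dict(block) for block in reg_data["regimens"])

    out_df = pd.read_csv(io.BytesIO(read("reference_outcomes.csv")), dtype={"regimen_id": str})
    outcomes = tuple(
        ReferenceOutcome(
            regimen_id=row.regimen_id,
            T_rm=float(row.T_rm),
            T_ro=float(row.T_ro),
            T_ro_range=(float(row.range_lo), float(row.range_hi)),
            deep_ratio=None if pd.isna(row.deep_ratio) else float(row.deep_ratio),
        )
        for row in out_df.itertuples()
    )

    ids = [r.regimen_id for r in records]
    if sorted(ids) != sorted(r.id for r in regimens) or len(set(ids)) != len(ids):
        raise ValueError("fixture regimen ids are inconsistent across files")

    return FixtureSet(
        study_records=records,
        regimens=regimens,
        reference_outcomes=outcomes,
        reference_patient=dict(reg_data["reference_patient"]),
    )
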