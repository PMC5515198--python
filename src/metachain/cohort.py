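"""Cohort data model and file I/O.

A cohort is a list of patient records, each carrying receptor status
(ER/HER2), vital status, follow-up time and a chronologically ordered
list of timed metastatic events. Times are years since initial breast
cancer diagnosis. Two serialisations are supported:

* ``json`` — a single document with one object per patient (lossless
  round-trip format);
* ``csv_pair`` — ``patients.csv`` + ``events.csv``, the shape registry
  extracts usually arrive in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .sites import BREAST, TAXONOMY, canonical_site

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

ER_STATUSES = ("positive", "negative", "unknown")
HER2_STATUSES = ("positive", "negative", "unknown")
VITAL_STATUSES = ("alive", "deceased")

#: Receptor-defined subgroups. ER+/HER2− and ER−/HER2− require a known
#: negative HER2; HER2+ overrides ER status.
SUBGROUPS = ("all", "er_pos_her2_neg", "er_neg_her2_neg", "her2_pos")


class SchemaError(ValueError):
    """Input file does not conform to the cohort schema."""


@dataclass(frozen=True)
class MetEvent:
    """A metastatic tumour detected at ``site``, ``time`` years after diagnosis."""

    site: str
    time: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be non-negative, got {self.time}")
        if self.site == BREAST:
            raise ValueError("metastatic events cannot occur at the primary (breast)")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    er_status: str
    her2_status: str
    vital_status: str
    followup_years: float
    events: tuple[MetEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.er_status not in ER_STATUSES:
            raise ValueError(f"bad er_status {self.er_status!r}")
        if self.her2_status not in HER2_STATUSES:
            raise ValueError(f"bad her2_status {self.her2_status!r}")
        if self.vital_status not in VITAL_STATUSES:
            raise ValueError(f"bad vital_status {self.vital_status!r}")
        if self.followup_years < 0:
            raise ValueError("followup_years must be non-negative")
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError(
                f"events of patient {self.patient_id} are not time-sorted"
            )

    @property
    def subgroup(self) -> str | None:
        """Receptor subgroup label, or None when status is insufficient."""
        if self.her2_status == "positive":
            return "her2_pos"
        if self.her2_status == "negative":
            if self.er_status == "positive":
                return "er_pos_her2_neg"
            if self.er_status == "negative":
                return "er_neg_her2_neg"
        return None

    @property
    def death_time(self) -> float | None:
        return self.followup_years if self.vital_status == "deceased" else None


@dataclass(frozen=True)
class Cohort:
    patients: tuple[PatientRecord, ...]
    taxonomy: tuple[str, ...] = TAXONOMY

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate patient_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.patients)


def _patient_from_dict(d: dict) -> PatientRecord:
    events = sorted(
        (MetEvent(canonical_site(e["site"]), float(e["time"])) for e in d.get("events", ())),
        key=lambda e: e.time,
    )
    return PatientRecord(
        patient_id=str(d["patient_id"]),
        er_status=d["er_status"],
        her2_status=d["her2_status"],
        vital_status=d["vital_status"],
        followup_years=float(d["followup_years"]),
        events=tuple(events),
    )


def _patient_to_dict(p: PatientRecord) -> dict:
    return {
        "patient_id": p.patient_id,
        "er_status": p.er_status,
        "her2_status": p.her2_status,
        "vital_status": p.vital_status,
        "followup_years": p.followup_years,
        "events": [{"site": e.site, "time": e.time} for e in p.events],
    }


_PATIENT_COLS = ("patient_id", "er_status", "her2_status", "vital_status", "followup_years")
_EVENT_COLS = ("patient_id", "site", "event_years")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing required column(s): {missing}")


def read_cohort(path: str | Path, fmt: str = "json") -> Cohort:
    """Read a cohort from disk.

    ``fmt='json'`` expects a single document; ``fmt='csv_pair'`` expects
    ``path`` to be a directory holding ``patients.csv`` and ``events.csv``.
    Unsorted event times are repaired with a warning; a duplicate
    patient id or a missing column raises :class:`SchemaError`.
    """
    path = Path(path)
    if fmt == "json":
        doc = json.loads(path.read_text())
        return Cohort(patients=tuple(_patient_from_dict(d) for d in doc["patients"]))
    if fmt == "csv_pair":
        pdf = pd.read_csv(path / "patients.csv", dtype={"patient_id": str})
        _require_columns(pdf, _PATIENT_COLS, "patients.csv")
        try:
            edf = pd.read_csv(path / "events.csv", dtype={"patient_id": str})
        except pd.errors.EmptyDataError:
            edf = pd.DataFrame(columns=_EVENT_COLS)
        _require_columns(edf, _EVENT_COLS, "events.csv")
        by_patient: dict[str, list[MetEvent]] = {}
        for row in edf.itertuples(index=False):
            by_patient.setdefault(row.patient_id, []).append(
                MetEvent(canonical_site(row.site), float(row.event_years))
            )
        patients = []
        for row in pdf.itertuples(index=False):
            events = by_patient.get(row.patient_id, [])
            if [e.time for e in events] != sorted(e.time for e in events):
                logger.warning(
                    "events of patient %s were not time-sorted; repaired", row.patient_id
                )
            events.sort(key=lambda e: e.time)
            patients.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    er_status=row.er_status,
                    her2_status=row.her2_status,
                    vital_status=row.vital_status,
                    followup_years=float(row.followup_years),
                    events=tuple(events),
                )
            )
        return Cohort(patients=tuple(patients))
    raise ValueError(f"unknown cohort format {fmt!r}")


def write_cohort(cohort: Cohort, path: str | Path, fmt: str = "json") -> None:
    """Write a cohort; JSON round-trips bit-identically through :func:`read_cohort`."""
    path = Path(path)
    if fmt == "json":
        doc = {"patients": [_patient_to_dict(p) for p in cohort.patients]}
        path.write_text(json.dumps(doc, indent=1))
        return
    if fmt == "csv_pair":
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {c: getattr(p, c) for c in _PATIENT_COLS}
                for p in cohort.patients
            ]
        ).to_csv(path / "patients.csv", index=False)
        pd.DataFrame(
            [
                {"patient_id": p.patient_id, "site": e.site, "event_years": e.time}
                for p in cohort.patients
                for e in p.events
            ],
            columns=list(_EVENT_COLS),
        ).to_csv(path / "events.csv", index=False)
        return
    raise ValueError(f"unknown cohort format {fmt!r}")


def filter_subgroup(cohort: Cohort, subgroup: str) -> Cohort:
    """Restrict a cohort to one receptor subgroup.

    ``all`` is the identity. Patients with unknown receptor status belong
    to no subgroup and are dropped from every subgroup other than ``all``.
    """
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    if subgroup == "all":
        return cohort
    return replace(
        cohort,
        patients=tuple(p for p in cohort.patients if p.subgroup == subgroup),
    )
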