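"""Extraction of metastatic pathways from timed event records.

A pathway is the ordered sequence of site-sets a patient's disease
visits, starting at the breast primary and, when death falls inside the
observation window, ending in the absorbing ``deceased`` state.
Metastases detected within a short tolerance of one another (imaging and
exams happen at 1–3 month intervals, so same-visit detections share a
date) are merged into a single site-set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import DAYS_PER_YEAR, Cohort, PatientRecord
from .sites import BREAST, DECEASED

#: Default merge tolerance for co-occurring metastases: 14 days.
DEFAULT_CO_TOLERANCE = 14.0 / DAYS_PER_YEAR

#: Default observation window, years.
DEFAULT_WINDOW = 10.0


@dataclass(frozen=True)
class Pathway:
    """Ordered site-set sequence; ``steps[0]`` is always ``{breast}``."""

    steps: tuple[frozenset[str], ...]
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if not self.steps or self.steps[0] != frozenset({BREAST}):
            raise ValueError("pathway must start with the {breast} step")
        for i, step in enumerate(self.steps):
            if not step:
                raise ValueError("empty site-set in pathway")
            if DECEASED in step and (i != len(self.steps) - 1 or len(step) != 1):
                raise ValueError("deceased must be the final singleton step")

    @property
    def terminal(self) -> bool:
        return self.steps[-1] == frozenset({DECEASED})

    @property
    def key(self) -> tuple[frozenset[str], ...]:
        """Equality key: the site-set sequence (patient identity ignored)."""
        return self.steps


def merge_events(times_sites, co_tolerance: float):
    """Group (time, site) pairs into site-sets.

    A new group starts whenever an event is more than ``co_tolerance``
    years after the first event of the current group; with tolerance 0
    any two distinct times split.
    """
    groups: list[tuple[float, set[str]]] = []
    for t, site in times_sites:
        if groups and t - groups[-1][0] <= co_tolerance:
            groups[-1][1].add(site)
        else:
            groups.append((t, {site}))
    return groups


def patient_pathway(
    patient: PatientRecord,
    window_years: float = DEFAULT_WINDOW,
    co_tolerance: float = DEFAULT_CO_TOLERANCE,
) -> Pathway | None:
    """Pathway of one patient within the observation window, or None if ineligible.

    Eligibility mirrors a fixed-window longitudinal study: either the
    patient was followed for at least ``window_years``, or they died
    before the window closed (their full progression is then known).
    Events after the window are truncated; death inside the window
    appends the terminal ``{deceased}`` step, ordered after any same-day
    metastasis.
    """
    died = patient.vital_status == "deceased"
    if not (patient.followup_years >= window_years or died):
        return None
    events = [(e.time, e.site) for e in patient.events if e.time <= window_years]
    steps: list[frozenset[str]] = [frozenset({BREAST})]
    steps.extend(frozenset(sites) for _, sites in merge_events(events, co_tolerance))
    if died and patient.followup_years <= window_years:
        steps.append(frozenset({DECEASED}))
    return Pathway(steps=tuple(steps), patient_id=patient.patient_id)


def extract_pathways(
    cohort: Cohort,
    window_years: float = DEFAULT_WINDOW,
    co_tolerance: float = DEFAULT_CO_TOLERANCE,
) -> list[Pathway]:
    """Pathways of every window-eligible patient in the cohort."""
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    if co_tolerance < 0:
        raise ValueError("co_tolerance must be non-negative")
    out = []
    for p in cohort.patients:
        pw = patient_pathway(p, window_years=window_years, co_tolerance=co_tolerance)
        if pw is not None:
            out.append(pw)
    return out


def count_distinct_pathways(pathways: list[Pathway]) -> int:
    """Number of unique site-set sequences (within-set order is irrelevant)."""
    return len({p.key for p in pathways})
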