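"""Survival analysis by first metastatic site, multiplicity and subgroup.

Survival time runs from initial breast cancer diagnosis (not from first
relapse) to death, right-censored at last follow-up. Kaplan–Meier
product-limit curves come from lifelines; the hazard ratio between two
groups is reported either as the incidence-rate ratio (exact under
exponential hazards, and the natural reading of "group A dies at twice
the rate of group B") or from the O/E log-rank decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort
from .pathways import DEFAULT_CO_TOLERANCE, DEFAULT_WINDOW, extract_pathways
from .sites import BREAST, DECEASED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalSample:
    """Per-subject follow-up times (years) and death indicators."""

    times: np.ndarray
    events: np.ndarray  # True = death observed, False = censored

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if times.size == 0:
            raise ValueError("survival sample needs at least one subject")
        if times.shape != events.shape:
            raise ValueError("times and events must be the same length")
        if (times < 0).any():
            raise ValueError("survival times must be non-negative")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def person_time(self) -> float:
        return float(self.times.sum())


@dataclass(frozen=True)
class KMCurve:
    """Kaplan–Meier product-limit curve (right-continuous step function)."""

    event_times: np.ndarray   # distinct death times, ascending
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # risk-set size at each event time
    n_deaths: np.ndarray      # deaths at each event time
    censor_times: np.ndarray  # censoring marks
    max_time: float


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Product-limit estimate: S(t) = Π_{t_i ≤ t} (1 − d_i / r_i).

    Deaths and censorings at the same instant follow the standard
    convention: deaths are processed first (censored subjects at t are
    still at risk at t).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, event_observed=sample.events)
    table = kmf.event_table
    death_rows = table[table["observed"] > 0]
    event_times = death_rows.index.to_numpy(dtype=float)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=death_rows["at_risk"].to_numpy(dtype=float),
        n_deaths=death_rows["observed"].to_numpy(dtype=float),
        censor_times=np.sort(sample.times[~sample.events]),
        max_time=float(sample.times.max()),
    )


def survival_at(curve: KMCurve, t: float) -> tuple[float, bool]:
    """S(t) by right-continuous step evaluation.

    Returns ``(probability, extrapolated)``; the flag is True when t lies
    beyond the last observed time, where the curve is carried forward.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    extrapolated = t > curve.max_time
    idx = np.searchsorted(curve.event_times, t, side="right")
    value = 1.0 if idx == 0 else float(curve.survival[idx - 1])
    return value, extrapolated


def km_curve_frame(curve: KMCurve) -> pd.DataFrame:
    """Curve as a tidy table (time, survival, at_risk, deaths)."""
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "deaths": curve.n_deaths,
        }
    )


def hazard_ratio(
    a: SurvivalSample, b: SurvivalSample, method: str = "rate_ratio"
) -> float:
    """Hazard ratio of group a over group b.

    ``rate_ratio``: (events_a / person-time_a) / (events_b / person-time_b);
    exact under exponential hazards. ``log_rank``: (O_a/E_a)/(O_b/E_b)
    from the log-rank expected-death decomposition over the pooled
    risk sets.
    """
    if method not in ("rate_ratio", "log_rank"):
        raise ValueError(f"unknown method {method!r}")
    if a.n_events == 0 or b.n_events == 0:
        raise ZeroDivisionError("hazard ratio undefined: a group has no events")
    if method == "rate_ratio":
        return (a.n_events / a.person_time) / (b.n_events / b.person_time)
    # log-rank O/E decomposition
    times = np.concatenate([a.times, b.times])
    events = np.concatenate([a.events, b.events])
    group = np.concatenate([np.zeros(a.n, dtype=int), np.ones(b.n, dtype=int)])
    e_a = e_b = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        dead_here = events & (times == t)
        r = at_risk.sum()
        d = dead_here.sum()
        r_a = (at_risk & (group == 0)).sum()
        r_b = (at_risk & (group == 1)).sum()
        e_a += d * r_a / r
        e_b += d * r_b / r
    return (a.n_events / e_a) / (b.n_events / e_b)


def _sample_from(patients) -> SurvivalSample:
    return SurvivalSample(
        times=np.array([p.followup_years for p in patients]),
        events=np.array([p.vital_status == "deceased" for p in patients]),
    )


def group_cohort(
    cohort: Cohort,
    by: str,
    window_years: float = DEFAULT_WINDOW,
    co_tolerance: float = DEFAULT_CO_TOLERANCE,
) -> dict[str, SurvivalSample]:
    """Partition window-eligible patients into named survival groups.

    ``first_site_solitary``: patients whose first relapse site-set is a
    singleton, grouped by that site (multi-site first relapses and
    metastasis-free patients are excluded). ``n_first_mets``: groups
    "1" / "2" / ">2" by the size of the first site-set.
    ``subgroup``: ER/HER2 receptor groups (unknown status excluded).
    Empty groups are omitted.
    """
    if by not in ("first_site_solitary", "n_first_mets", "subgroup"):
        raise ValueError(f"unknown grouping {by!r}")
    eligible_ids = {
        pw.patient_id: pw
        for pw in extract_pathways(cohort, window_years, co_tolerance)
    }
    groups: dict[str, list] = {}
    for p in cohort.patients:
        pw = eligible_ids.get(p.patient_id)
        if pw is None:
            continue
        if by == "subgroup":
            key = p.subgroup
            if key is None:
                continue
        else:
            mets = [s for s in pw.steps[1:] if s != frozenset({DECEASED})]
            if not mets:
                continue
            first = mets[0]
            if by == "first_site_solitary":
                if len(first) != 1:
                    continue
                key = next(iter(first))
            else:
                key = "1" if len(first) == 1 else ("2" if len(first) == 2 else ">2")
        groups.setdefault(key, []).append(p)
    return {k: _sample_from(v) for k, v in groups.items() if v}


def mean_sites_at_death(cohort: Cohort) -> float:
    """Mean number of distinct metastatic sites at death, over deceased patients.

    Breast and the deceased state itself are not counted.
    """
    counts = [
        len({e.site for e in p.events} - {BREAST, DECEASED})
        for p in cohort.patients
        if p.vital_status == "deceased"
    ]
    if not counts:
        raise ValueError("no deceased patients: mean sites at death undefined")
    return float(np.mean(counts))
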