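"""Time-to-event samples and two-parameter Weibull maximum likelihood.

The chain's ordinal time step k is linked to calendar time through the
distributions of diagnosis-to-k-th-metastasis times (and diagnosis to
first metastasis at a named site), each summarised by a two-parameter
Weibull fit. Fitting maximises the uncensored Weibull likelihood via
profile likelihood: for fixed shape k the scale MLE is closed form,

    λ̂(k)^k = mean(t_i^k),

and the shape solves the 1-D score equation

    Σ t_i^k log t_i / Σ t_i^k − 1/k − mean(log t_i) = 0,

whose left side is monotone increasing in k, so a bracketing root find
is deterministic. The fit is of realised (observed-event) times only;
subjects without the event are excluded rather than censored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import gamma as gamma_fn

from .cohort import Cohort
from .pathways import DEFAULT_CO_TOLERANCE, merge_events
from .sites import BREAST, DECEASED

SHAPE_TOL = 1e-8


@dataclass(frozen=True)
class WeibullFit:
    shape: float
    scale: float
    loglik: float
    n: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    @property
    def mean(self) -> float:
        """Implied mean λ·Γ(1 + 1/k), years."""
        return self.scale * gamma_fn(1.0 + 1.0 / self.shape)

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "scale": self.scale,
            "mean_years": self.mean,
            "loglik": self.loglik,
            "n": self.n,
            "converged": self.converged,
        }


def weibull_loglik(times: np.ndarray, shape: float, scale: float) -> float:
    t = np.asarray(times, dtype=float)
    z = t / scale
    return float(
        t.size * (np.log(shape) - np.log(scale))
        + (shape - 1) * np.log(z).sum()
        - (z**shape).sum()
    )


def moment_shape_start(times: np.ndarray) -> float:
    """Method-of-moments starting shape from the coefficient of variation.

    Uses the approximation k ≈ (sd/mean)^(-1.086), standard for Weibull
    initialisation; clipped to a sane bracket.
    """
    t = np.asarray(times, dtype=float)
    cv = t.std() / t.mean()
    if cv <= 0:
        return 1.0
    return float(np.clip(cv ** (-1.086), 0.05, 50.0))


def weibull_mle(times) -> WeibullFit:
    """Two-parameter Weibull MLE of a sample of positive times."""
    t = np.asarray(times, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 observations for a Weibull fit")
    if (t <= 0).any():
        raise ValueError("all times must be strictly positive")
    logt = np.log(t)
    mean_logt = logt.mean()

    def score(k: float) -> float:
        tk = t**k
        return float((tk * logt).sum() / tk.sum() - 1.0 / k - mean_logt)

    k0 = moment_shape_start(t)
    lo, hi = k0, k0
    # widen the bracket around the moment start until the score changes sign
    for _ in range(80):
        if score(lo) < 0:
            break
        lo /= 1.5
    for _ in range(80):
        if score(hi) > 0:
            break
        hi *= 1.5
    converged = score(lo) < 0 < score(hi)
    if converged:
        shape = float(optimize.brentq(score, lo, hi, xtol=SHAPE_TOL))
    else:  # pathological sample (e.g. all times equal); report the start
        shape = k0
    scale = float(np.mean(t**shape) ** (1.0 / shape))
    return WeibullFit(
        shape=shape,
        scale=scale,
        loglik=weibull_loglik(t, shape, scale),
        n=int(t.size),
        converged=converged,
    )


def time_to_event_sample(
    cohort: Cohort,
    target: str | int,
    co_tolerance: float = DEFAULT_CO_TOLERANCE,
) -> np.ndarray:
    """Diagnosis-to-event times for a temporal target.

    ``target`` is either an integer k ≥ 1 — the time of each patient's
    k-th metastatic step (co-occurring events merged into one step, the
    step timed at its first event) — or a site label — the time of the
    first metastasis at that site. Patients without the event are
    excluded.
    """
    out: list[float] = []
    if isinstance(target, int):
        if target < 1:
            raise ValueError("k-th metastasis index must be ≥ 1")
        for p in cohort.patients:
            groups = merge_events([(e.time, e.site) for e in p.events], co_tolerance)
            if len(groups) >= target:
                out.append(groups[target - 1][0])
    else:
        if target in (BREAST, DECEASED):
            raise ValueError(f"{target!r} is not a metastatic site")
        for p in cohort.patients:
            for e in p.events:
                if e.site == target:
                    out.append(e.time)
                    break
    return np.asarray(out, dtype=float)


def fit_report(target: str, fit: WeibullFit, sample: np.ndarray) -> dict:
    """JSON-ready fit summary; reports both the fitted and the sample mean."""
    return {
        "target": target,
        "n": fit.n,
        "shape": fit.shape,
        "scale": fit.scale,
        "mean_years": fit.mean,
        "sample_mean_years": float(np.mean(sample)),
        "loglik": fit.loglik,
    }


def write_fit_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
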