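"""Empirical Markov-chain estimation and propagation.

The disease model is a discrete-time Markov chain v_{k+1} = v_k A on the
anatomical site taxonomy, with the breast primary as origin and
``deceased`` as the absorbing state. A is estimated by simple
denumeration of progression events: each observed transition from one
site-set to the next contributes counts, and rows are normalised to
probabilities. The time step k is event-ordinal (one metastatic step),
not calendar time; calendar calibration lives in the temporal module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pathways import Pathway
from .sites import BREAST, DECEASED, TAXONOMY

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix with its underlying counts.

    ``probs[i, j]`` is the probability that the next metastatic event
    after disease at site i occurs at site j; ``counts`` holds the
    (possibly fractional, for multi-site steps) denumeration tallies.
    """

    sites: tuple[str, ...]
    probs: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        n = len(self.sites)
        if probs.shape != (n, n):
            raise ValueError(f"probs must be {n}x{n}, got {probs.shape}")
        if (probs < -ROW_SUM_TOL).any() or (probs > 1 + ROW_SUM_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=ROW_SUM_TOL):
            bad = [self.sites[i] for i in np.nonzero(~np.isclose(row_sums, 1, atol=ROW_SUM_TOL))[0]]
            raise ValueError(f"rows must sum to 1; offending rows: {bad}")
        if DECEASED in self.sites:
            d = self.sites.index(DECEASED)
            expected = np.zeros(n)
            expected[d] = 1.0
            if not np.allclose(probs[d], expected, atol=ROW_SUM_TOL):
                raise ValueError("deceased row must be absorbing")

    def __getitem__(self, key: tuple[str, str]) -> float:
        i, j = key
        return float(self.probs[self.sites.index(i), self.sites.index(j)])

    def row(self, site: str) -> dict[str, float]:
        i = self.sites.index(site)
        return {s: float(p) for s, p in zip(self.sites, self.probs[i])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(self.sites), columns=list(self.sites))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), index_label="site")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionMatrix":
        df = pd.read_csv(Path(path), index_col=0)
        return cls(sites=tuple(df.index), probs=df.to_numpy(dtype=float))

    def to_json(self, path: str | Path) -> None:
        doc = {"sites": list(self.sites), "probs": self.probs.tolist()}
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionMatrix":
        doc = json.loads(Path(path).read_text())
        return cls(sites=tuple(doc["sites"]), probs=np.asarray(doc["probs"], dtype=float))


@dataclass(frozen=True)
class StateVector:
    """Probability distribution over anatomical sites after k model steps."""

    sites: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (len(self.sites),):
            raise ValueError("state vector length must match taxonomy")
        if (probs < -ROW_SUM_TOL).any():
            raise ValueError("state probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > ROW_SUM_TOL:
            raise ValueError(f"state vector must sum to 1, got {probs.sum()}")

    def __getitem__(self, site: str) -> float:
        return float(self.probs[self.sites.index(site)])


def initial_state(taxonomy: tuple[str, ...] = TAXONOMY) -> StateVector:
    """v_0: all probability mass on the breast primary."""
    v = np.zeros(len(taxonomy))
    v[taxonomy.index(BREAST)] = 1.0
    return StateVector(sites=taxonomy, probs=v)


def tally_transitions(
    pathways: list[Pathway], taxonomy: tuple[str, ...] = TAXONOMY
) -> np.ndarray:
    """Denumeration of site-to-site progression events.

    For each consecutive pair of site-sets S -> T, every site t in T
    contributes one unit of count, split equally over the sites of S
    (fractional counts preserve total transition mass = |T|). A repeat
    tumour at an already-affected site tallies as a self-transition.
    """
    idx = {s: i for i, s in enumerate(taxonomy)}
    counts = np.zeros((len(taxonomy), len(taxonomy)))
    for pw in pathways:
        for prev, nxt in zip(pw.steps, pw.steps[1:]):
            w = 1.0 / len(prev)
            for s in prev:
                for t in nxt:
                    counts[idx[s], idx[t]] += w
    return counts


def estimate_transition_matrix(
    pathways: list[Pathway],
    taxonomy: tuple[str, ...] = TAXONOMY,
    smoothing: str = "none",
) -> TransitionMatrix:
    """Estimate A by row-normalising the denumeration tallies.

    Non-deceased rows with no observed exits become self-absorbing with a
    warning (``smoothing='none'``) or receive one pseudo-count per
    reachable column (``smoothing='add_one'``; the breast column stays
    zero — there is no return flow to the primary). The deceased row is
    always forced absorbing.
    """
    if smoothing not in ("none", "add_one"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    if not pathways:
        raise ValueError("cannot estimate a transition matrix from zero pathways")
    if not any(len(p.steps) > 1 for p in pathways):
        raise ValueError("need at least one pathway with a step beyond breast")
    counts = tally_transitions(pathways, taxonomy)
    n = len(taxonomy)
    d = taxonomy.index(DECEASED)
    b = taxonomy.index(BREAST)
    probs = np.zeros((n, n))
    for i in range(n):
        if i == d:
            continue
        row = counts[i].copy()
        if row.sum() == 0:
            if smoothing == "add_one":
                row = np.ones(n)
                row[b] = 0.0
            else:
                logger.warning(
                    "site %r has no observed exits; made self-absorbing", taxonomy[i]
                )
                row[i] = 1.0
        probs[i] = row / row.sum()
    probs[d] = 0.0
    probs[d, d] = 1.0
    return TransitionMatrix(sites=tuple(taxonomy), probs=probs, counts=counts)


def propagate(v: StateVector, A: TransitionMatrix, k: int) -> StateVector:
    """k-step propagation v A^k of the site-occupancy distribution."""
    if v.sites != A.sites:
        raise ValueError("state vector and matrix must share the same taxonomy")
    if k < 0:
        raise ValueError("k must be non-negative")
    out = v.probs.copy()
    for _ in range(k):
        out = out @ A.probs
    return StateVector(sites=v.sites, probs=out)


@dataclass(frozen=True)
class NextStepDistribution:
    """Empirical next-step distribution after a pathway prefix."""

    prefix: tuple[str, ...]
    probs: dict[str, float]
    n_matching: int


def conditional_next_distribution(
    pathways: list[Pathway], prefix: tuple[str, ...] | list[str]
) -> NextStepDistribution:
    """Distribution of the next site visited after a given singleton prefix.

    A pathway matches when its first ``len(prefix)`` steps are exactly
    the singleton site-sets of ``prefix``. Among matching pathways that
    progress further, the next step's sites are tallied (a multi-site
    step splits its unit mass equally). Matching pathways that end at
    the prefix carry no next-step information and are excluded from the
    count. An empty match yields an empty distribution with count 0.
    """
    prefix = tuple(prefix)
    if not prefix or prefix[0] != BREAST:
        raise ValueError("prefix must begin with breast")
    wanted = tuple(frozenset({s}) for s in prefix)
    mass: dict[str, float] = {}
    n = 0
    for pw in pathways:
        if len(pw.steps) <= len(prefix):
            continue
        if pw.steps[: len(prefix)] != wanted:
            continue
        n += 1
        nxt = pw.steps[len(prefix)]
        for site in nxt:
            mass[site] = mass.get(site, 0.0) + 1.0 / len(nxt)
    total = sum(mass.values())
    probs = {s: m / total for s, m in sorted(mass.items())} if total else {}
    return NextStepDistribution(prefix=prefix, probs=probs, n_matching=n)
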