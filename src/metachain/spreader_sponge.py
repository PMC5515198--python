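"""Spreader/sponge classification of metastatic sites.

Two-step pathways breast -> i -> j carry probability a(breast,i)·a(i,j).
A site's *amplification factor* is the ratio of the two-step probability
mass flowing out of it (as intermediate) to the mass flowing into it
(as terminal): factor > 1 marks a net exporter of progression — a
"spreader" — and factor < 1 a net absorber — a "sponge". A one-step
variant (plain row/column mass ratio) is provided for sensitivity
analysis, since published descriptions of the factor mix the two
readings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .markov import TransitionMatrix
from .sites import BREAST, DECEASED


@dataclass(frozen=True)
class TwoStepPathway:
    intermediate: str
    terminal: str
    probability: float


@dataclass(frozen=True)
class SiteFlow:
    site: str
    outgoing_mass: float
    incoming_mass: float
    factor: float | None  # None when incoming mass is zero (undefined)
    label: str  # spreader | sponge | neutral | undefined


@dataclass(frozen=True)
class SpreaderSpongeResult:
    mode: str
    flows: tuple[SiteFlow, ...]

    def __getitem__(self, site: str) -> SiteFlow:
        for f in self.flows:
            if f.site == site:
                return f
        raise KeyError(site)

    @property
    def spreaders(self) -> tuple[str, ...]:
        return tuple(f.site for f in self.flows if f.label == "spreader")

    @property
    def sponges(self) -> tuple[str, ...]:
        return tuple(f.site for f in self.flows if f.label == "sponge")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "mode": self.mode,
            "sites": [
                {
                    "site": f.site,
                    "outgoing": f.outgoing_mass,
                    "incoming": f.incoming_mass,
                    "factor": f.factor,
                    "label": f.label,
                }
                for f in self.flows
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))


NEUTRAL_TOL = 1e-12


def _intermediates(sites: tuple[str, ...]) -> list[str]:
    return [s for s in sites if s not in (BREAST, DECEASED)]


def enumerate_two_step_pathways(
    A: TransitionMatrix, top_n: int | None = None
) -> tuple[list[TwoStepPathway], float]:
    """All breast -> i -> j pathways, sorted by probability.

    Returns the ``top_n`` pathways (ties broken by taxonomy order, so
    sorting is deterministic) together with the *coverage*: the
    percentage of the total two-step probability mass they represent.
    ``top_n=None`` enumerates everything (coverage 100).
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be at least 1")
    sites = A.sites
    b = sites.index(BREAST)
    order = {s: k for k, s in enumerate(sites)}
    all_paths = []
    for i, si in enumerate(sites):
        if si in (BREAST, DECEASED):
            continue
        for j, sj in enumerate(sites):
            p = float(A.probs[b, i] * A.probs[i, j])
            all_paths.append(TwoStepPathway(si, sj, p))
    all_paths.sort(
        key=lambda t: (-t.probability, order[t.intermediate], order[t.terminal])
    )
    total = sum(t.probability for t in all_paths)
    chosen = all_paths if top_n is None else all_paths[:top_n]
    kept = sum(t.probability for t in chosen)
    coverage = 100.0 * kept / total if total > 0 else 100.0
    return chosen, coverage


def classify_sites(A: TransitionMatrix, mode: str = "two_step") -> SpreaderSpongeResult:
    """Label each metastatic site spreader / sponge / neutral.

    ``two_step`` (default): outgoing(s) = Σ_j a(breast,s)·a(s,j),
    incoming(s) = Σ_i a(breast,i)·a(i,s) over intermediates i.
    ``one_step``: outgoing(s) = Σ_{j≠s} a(s,j), incoming(s) = Σ_{i≠s} a(i,s).
    Breast and deceased are outside the dichotomy and never labelled; a
    site with zero incoming mass has an undefined factor and is flagged.
    """
    if mode not in ("two_step", "one_step"):
        raise ValueError(f"unknown mode {mode!r}")
    sites = A.sites
    b = sites.index(BREAST)
    P = A.probs
    inter = _intermediates(sites)
    flows = []
    for s in inter:
        k = sites.index(s)
        if mode == "two_step":
            outgoing = float(P[b, k] * P[k].sum())
            incoming = float(
                sum(P[b, sites.index(i)] * P[sites.index(i), k] for i in inter)
            )
        else:
            outgoing = float(P[k].sum() - P[k, k])
            incoming = float(P[:, k].sum() - P[k, k])
        if incoming <= 0.0:
            factor, label = None, "undefined"
        else:
            factor = outgoing / incoming
            if abs(factor - 1.0) <= NEUTRAL_TOL:
                label = "neutral"
            elif factor > 1.0:
                label = "spreader"
            else:
                label = "sponge"
        flows.append(SiteFlow(s, outgoing, incoming, factor, label))
    return SpreaderSpongeResult(mode=mode, flows=tuple(flows))


def site_exit_distribution(
    A: TransitionMatrix, site: str, top_k: int | None = None
) -> tuple[list[tuple[str, float]], float]:
    """One-step exit profile of a site: its matrix row, sorted descending.

    Returns the ``top_k`` destinations (ties broken by taxonomy order)
    and the percentage of the row's mass they retain.
    """
    if site not in A.sites:
        raise ValueError(f"unknown site {site!r}")
    if site == DECEASED:
        raise ValueError("the absorbing deceased row is not an exit profile")
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be at least 1")
    i = A.sites.index(site)
    entries = [
        (s, float(p)) for s, p in zip(A.sites, A.probs[i])
    ]
    order = {s: k for k, s in enumerate(A.sites)}
    entries.sort(key=lambda e: (-e[1], order[e[0]]))
    chosen = entries if top_k is None else entries[:top_k]
    retained = 100.0 * sum(p for _, p in chosen)  # row sums to 1
    return chosen, retained


def chord_diagram_data(A: TransitionMatrix, min_probability: float = 0.0) -> dict:
    """Nodes/links document for chord or sankey renderers."""
    links = [
        {"source": si, "target": sj, "probability": float(A.probs[i, j])}
        for i, si in enumerate(A.sites)
        for j, sj in enumerate(A.sites)
        if si != DECEASED and A.probs[i, j] > min_probability
    ]
    return {"nodes": list(A.sites), "links": links}
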