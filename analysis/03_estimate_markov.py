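#!/usr/bin/env python
"""Estimate the Markov transition matrix and conditional relapse flows.

Denumerates site-to-site progression events over the eligible pathways,
writes the estimated matrix per subgroup, propagates the chain from the
all-breast initial state, and contrasts the empirical next-step
distributions after the breast-bone-lung versus breast-bone-liver
prefixes.
"""

import json
from pathlib import Path

from metachain import (
    Pathway,
    conditional_next_distribution,
    estimate_transition_matrix,
    initial_state,
    propagate,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_pathways(group):
    doc = json.loads((RESULTS / f"pathways_{group}.json").read_text())
    return [
        Pathway(steps=tuple(frozenset(s) for s in p["steps"]), patient_id=p["patient_id"])
        for p in doc["pathways"]
    ]


def main() -> None:
    for group in ("all", "er_pos_her2_neg", "er_neg_her2_neg", "her2_pos"):
        pathways = load_pathways(group)
        A = estimate_transition_matrix(pathways)
        A.to_csv(RESULTS / f"transition_matrix_{group}.csv")
        print(f"{group}: a(breast,bone) = {A['breast','bone']:.3f}")

    pathways = load_pathways("all")
    A = estimate_transition_matrix(pathways)
    v = initial_state()
    for k in (1, 2, 3):
        vk = propagate(v, A, k)
        print(f"  deceased mass after {k} steps: {vk['deceased']:.3f}")
    for prefix in (("breast", "bone", "lung_pleura"), ("breast", "bone", "liver")):
        d = conditional_next_distribution(pathways, prefix)
        top = sorted(d.probs.items(), key=lambda kv: -kv[1])[:3]
        shown = ", ".join(f"{s} {p:.2f}" for s, p in top)
        print(f"  after {'-'.join(prefix)} (n={d.n_matching}): {shown}")
    report = {
        "-".join(prefix): {
            "n": conditional_next_distribution(pathways, prefix).n_matching,
            "probs": conditional_next_distribution(pathways, prefix).probs,
        }
        for prefix in (("breast", "bone", "lung_pleura"), ("breast", "bone", "liver"))
    }
    (RESULTS / "conditional_next.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
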