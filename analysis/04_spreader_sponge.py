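#!/usr/bin/env python
"""Classify metastatic sites as spreaders or sponges.

From the estimated all-patients matrix: enumerates the top-30 two-step
pathways out of the breast, computes each site's amplification factor
(outgoing over incoming two-step probability mass), labels sites, and
writes the per-site exit profiles and the chord-diagram data.
"""

import json
from pathlib import Path

from metachain import (
    TransitionMatrix,
    chord_diagram_data,
    classify_sites,
    enumerate_two_step_pathways,
    site_exit_distribution,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    A = TransitionMatrix.from_csv(RESULTS / "transition_matrix_all.csv")
    top30, coverage = enumerate_two_step_pathways(A, top_n=30)
    print(f"top 30 two-step pathways cover {coverage:.1f}% of total pathway mass")
    result = classify_sites(A, mode="two_step")
    for f in result.flows:
        factor = "undef" if f.factor is None else f"{f.factor:.3f}"
        print(f"  {f.site:12s} factor={factor:>7s}  {f.label}")
    result.to_json(RESULTS / "spreader_sponge.json")
    (RESULTS / "two_step_top30.json").write_text(json.dumps(
        [{"intermediate": p.intermediate, "terminal": p.terminal,
          "probability": p.probability} for p in top30], indent=1))
    (RESULTS / "chord_diagram.json").write_text(
        json.dumps(chord_diagram_data(A, min_probability=0.0), indent=1))

    exits = {}
    for site in ("bone", "chest_wall", "ln_mammary", "lung_pleura", "ln_distant", "liver"):
        dist, retained = site_exit_distribution(A, site, top_k=9)
        exits[site] = {"destinations": dist, "retained_pct": retained}
    (RESULTS / "site_exits.json").write_text(json.dumps(exits, indent=1))
    dist, _ = site_exit_distribution(A, "bone", top_k=3)
    print("  bone exits:", ", ".join(f"{s} {p:.2f}" for s, p in dist))


if __name__ == "__main__":
    main()
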