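#!/usr/bin/env python
"""Kaplan-Meier survival by subgroup, first metastatic site and multiplicity.

Groups the window-eligible patients three ways (receptor subgroup,
solitary first metastatic site, number of first-relapse metastases),
writes each group's product-limit curve, reports 10-year survival, and
the mean number of distinct metastatic sites at death.
"""

from pathlib import Path

from metachain import (
    group_cohort,
    hazard_ratio,
    km_curve_frame,
    km_estimate,
    mean_sites_at_death,
    read_cohort,
    survival_at,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.json")
    outdir = RESULTS / "km"
    outdir.mkdir(parents=True, exist_ok=True)
    samples = {}
    for by in ("subgroup", "first_site_solitary", "n_first_mets"):
        groups = group_cohort(cohort, by=by)
        print(f"grouping by {by}:")
        for name, s in sorted(groups.items()):
            curve = km_estimate(s)
            s10, _ = survival_at(curve, 10.0)
            fname = outdir / f"{by}_{name.replace('>', 'gt')}.csv"
            km_curve_frame(curve).to_csv(fname, index=False)
            print(f"  {name:16s} n={s.n:4d} deaths={s.n_events:3d} S(10y)={s10:.2f}")
            samples[(by, name)] = s
    pair = (("first_site_solitary", "liver"), ("first_site_solitary", "bone"))
    if all(k in samples for k in pair):
        hr = hazard_ratio(samples[pair[0]], samples[pair[1]])
        print(f"hazard ratio, liver-first over bone-first: {hr:.2f}")
    print(f"mean distinct metastatic sites at death: {mean_sites_at_death(cohort):.2f}")


if __name__ == "__main__":
    main()
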