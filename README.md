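# metachain

Markov-chain analysis of metastatic breast cancer progression.

Breast cancer disseminates from the primary tumour to a small set of
anatomical sites (bone, chest wall, lymph nodes, lung/pleura, liver,
brain, ...), and the order in which those sites are hit carries
prognostic information. This package models progression as a
discrete-time random walk on a directed site graph: a state vector
v_k holds the probability of a metastatic tumour at each of the n
sites after k steps and evolves as

    v_{k+1} = v_k A,

where A is an n×n row-stochastic transition matrix whose entry a_ij is
the probability that disease at site i next spreads to site j. The
walk starts with all mass on the breast (v_0 = (1, 0, 0, ...)) and
absorbs in a terminal `deceased` state. A is estimated empirically by
*denumeration*: counting observed site-to-site progression events in a
longitudinal cohort (if 36 of 100 tracked patients first relapse in
bone, a(breast, bone) = 0.36) and normalising rows.

On top of the chain the package provides:

- **pathway extraction** — per-patient site-set sequences over a fixed
  observation window (default 10 years; patients qualify by long
  follow-up or by death inside the window), with same-date metastases
  merged into co-occurring site-sets;
- **spreader/sponge classification** — a site's amplification factor is
  its outgoing two-step probability mass (breast → s → anywhere)
  divided by its incoming mass (breast → anywhere → s); factor > 1
  marks a net exporter of progression ("spreader"), factor < 1 a net
  absorber ("sponge");
- **survival analysis** — Kaplan–Meier product-limit curves grouped by
  receptor subgroup (ER+/HER2−, ER−/HER2−, HER2+), solitary first
  metastatic site, or number of first-relapse metastases, plus
  rate-ratio and log-rank hazard ratios;
- **temporal calibration** — two-parameter Weibull maximum-likelihood
  fits of diagnosis-to-k-th-metastasis times (implied mean
  λ·Γ(1 + 1/k));
- **diagram-ready exports** — sunburst ring-diagram trees and chord
  nodes/links JSON;
- **a synthetic cohort generator** — timed random walks on configurable
  per-subgroup transition matrices with Weibull waiting times,
  multi-site first relapses and administrative censoring, calibrated so
  its defaults emulate the published cohort summaries. Clinical
  registries of this kind are not public, so the generator is what
  makes every stage testable end to end.

## Worked example

```python
import metachain as mc

cfg = mc.default_config(seed=1)          # 446 patients, calibrated defaults
cohort = mc.simulate_cohort(cfg)
pathways = mc.extract_pathways(cohort)   # 10-year window
A = mc.estimate_transition_matrix(pathways)
print(len(pathways), mc.count_distinct_pathways(pathways))
print(round(A["breast", "bone"], 3))
res = mc.classify_sites(A)
print(res.spreaders, res.sponges)
fit = mc.weibull_mle(mc.sample_met_times(cfg, k=1, n=5000))
print(round(fit.mean, 2))
```

prints

```
387 227
0.3
('bone', 'chest_wall', 'ln_mammary', 'other') ('ln_distant', 'lung_pleura', 'liver', 'brain')
5.29
```

387 of the 446 simulated patients qualify for the 10-year window and
trace 227 distinct pathways. The estimated breast→bone entry (0.30)
sits below the configured 0.35 because multi-site first relapses
dilute the bone share of first-transition counts. Bone, chest wall and
the mammary lymph nodes come out as spreaders and lung/pleura, distant
lymph nodes, liver and brain as sponges — the flow structure the
defaults were calibrated to. The Weibull fit of 5 000 uncensored
first-metastasis waiting times recovers the configured 5.30-year mean.

The same pipeline is laid out as numbered drivers under `analysis/`
(simulate → pathways/rings → Markov estimation → spreader/sponge →
survival → temporal fits), each writing its tables to `results/`. A
thin CLI mirrors the steps: `metachain simulate|pathways|estimate|
classify|survival|temporal|rings`.

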