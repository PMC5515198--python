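# Methods

## Model

Disease progression is a discrete-time Markov chain on a closed
taxonomy of ten states: the breast primary, eight metastatic locations
(bone, chest wall, mammary and distant lymph nodes, lung/pleura,
liver, brain, a catch-all `other`), and an absorbing `deceased` state.
The state vector v_k — the probability of a metastatic tumour at each
site after k steps — evolves as v_{k+1} = v_k A with v_0 concentrated
on the breast. The step index k is *event-ordinal* (one metastatic
step per transition); calendar time enters separately through the
waiting-time distributions fitted in the temporal module. The Markov
assumption — the next site depends only on the current one, not on the
route taken — is a deliberate simplification: it is what makes the
chain estimable from a few hundred patients, and conditional next-step
distributions (`conditional_next_distribution`) are the tool for
probing where it strains.

## Pathway extraction

A patient enters the analysis window (default 10 years from diagnosis)
if followed at least that long or dead before the window closes — the
two cases in which their progression over the window is fully known.
Events after the window are truncated; death inside the window appends
the terminal `{deceased}` step, ordered after any same-day metastasis.
Metastases detected within 14 days of one another (0.0383 y; exams and
imaging happen at 1–3-month intervals, so same-visit detections share
a date) merge into one co-occurring site-set; the tolerance is a
parameter and 0 disables merging. Repeat metastases at an
already-affected site are retained — the network allows return flow.

## Estimation

`estimate_transition_matrix` counts transitions between consecutive
site-sets. A multi-site step S → T contributes one unit per site of T,
split equally over the sites of S (fractional counts; total transition
mass equals |T|). Rows are normalised to probabilities. A non-deceased
row with no observed exits becomes self-absorbing with a warning
(default) or, with `smoothing="add_one"`, receives one pseudo-count
per column except breast — the breast column is structurally zero
because there is no return to the primary. The deceased row is always
forced absorbing. The multi-site splitting rule and the singleton
prefix-matching used by `conditional_next_distribution` are this
package's conventions; registry practice for same-date multi-site
presentations is not standardised.

## Spreader/sponge classification

With b the breast row, a site s has outgoing two-step mass
Σ_j b_s·a_sj = b_s and incoming mass Σ_i b_i·a_is (i ranging over
metastatic intermediates, s itself included). The amplification factor
outgoing/incoming exceeds 1 for net exporters (spreaders) and falls
below 1 for net absorbers (sponges); breast and deceased sit outside
the dichotomy, and a site no two-step path reaches is flagged
undefined rather than labelled. Published verbal definitions of the
factor read as a one-step statement while the figure-level definition
is two-step; the two-step form is the default and a one-step variant
(`mode="one_step"`, plain off-diagonal row/column mass ratio) is
provided for sensitivity analysis. The neutral band is |factor − 1| ≤
1e-12 exactly — data-driven factors are generically different from 1,
so a fuzzy band would only hide information.

## Survival

Survival time runs from initial diagnosis (an option allows a
first-metastasis origin for exploration), right-censored at last
follow-up. Product-limit curves are computed via lifelines'
`KaplanMeierFitter`; ties between deaths and censorings resolve
deaths-first (the standard convention). The default hazard ratio is
the incidence-rate ratio (events per person-year), exact under
exponential hazards and matching the "dies at twice the rate" reading;
an O/E log-rank decomposition is the alternative. Cox regression is
deliberately absent — no covariate adjustment is needed for these
groupings. Multiplicity groups are fixed at {1, 2, >2} first-relapse
metastases. `mean_sites_at_death` counts distinct metastatic sites
(excluding breast and the deceased state) over deceased patients only.

## Temporal fits

Diagnosis-to-event samples are *observed-event* samples: patients
without the event are excluded, and no censored likelihood is used —
the fits describe realised relapse-time histograms, not the latent
distribution under censoring (the analysis driver prints both fitted
and sample means and flags the truncation). The two-parameter Weibull
MLE uses profile likelihood: for fixed shape k the scale MLE is
λ̂(k)^k = mean(t^k), and k solves the monotone 1-D score equation,
bracketed from a method-of-moments start (k ≈ CV^−1.086) and solved by
Brent's method to 1e-8 — deterministic given the data. Degenerate
samples (all times equal) are returned at the moment start with
`converged=False`. Maximum likelihood rather than histogram
least-squares is an interpretation: it is the statistically standard
way to fit a named parametric family to realised times.

## Synthetic cohort generator

Each simulated patient draws a receptor subgroup
(218/70/62 proportions over ER+/HER2−, ER−/HER2−, HER2+), then walks
their subgroup's transition matrix from breast until absorption,
with inter-event waiting times Weibull(shape 1.5, mean 5.30 y) for the
first step and Weibull(shape 1.4, mean 2.28 y) thereafter — so
diagnosis-to-second-metastasis averages 7.58 y. Administrative
censoring is uniform on [8, 20] years, chosen to exercise both window
eligibility branches (long follow-up and early death). First relapses
are multi-site with probability 0.3 (set sizes 1/2/≥3 weighted
0.7/0.2/0.1); extra sites are drawn without replacement from the
breast row with deceased excluded, and the walk continues from the
first-drawn site.

The default matrices are **calibration constants, not published
values**: the breast rows match the printed first-metastasis
percentages and orderings per subgroup (all ≈ 0.35 bone; ER+/HER2−
0.40 bone with distant lymph nodes second; ER−/HER2− 0.27 bone;
HER2+ 0.33 bone with lung/pleura second, chest wall third), and the
interior rows — nowhere published — were chosen once so the implied
flow reproduces the qualitative structure: spreaders bone, chest wall
and mammary lymph nodes; sponges lung/pleura, distant lymph nodes,
liver and brain; lung/pleura the leading exit from bone; a benign
breast–bone–lung continuation (lung row: liver 0.45, deceased 0.03)
against a dangerous breast–bone–liver one (liver row: deceased 0.35,
distant lymph nodes 0.31). Subgroup matrices differ from the
all-patients matrix only in the breast row. Weibull shapes are this
package's choice (only means are published); 1.5/1.4 give the mild
right skew typical of relapse-latency histograms.

What the generator does *not* emulate: treatment effects on transition
rates, age or stage covariates, site-dependent waiting times (one
shared step-time model by default, per-edge overrides supported),
inter-patient frailty, and diagnostic-interval discretisation of event
dates. Tests passing on synthetic cohorts therefore validate the
estimators and the pipeline plumbing — recovery of known parameters,
invariances, classification logic — not clinical conclusions about any
real registry.

## Numerical choices and problem sizes

Row-stochasticity is enforced to 1e-9; two-step sorting breaks ties by
taxonomy order so exports are deterministic; ring-diagram arc
percentages are normalised to the full eligible cohort (sectors shrink
outward), and co-occurring sets get a sorted "+"-joined sector label.
Simulation-backed tests use 2 000–5 000 patients or draws with 3-SE
binomial/normal envelopes and fixed seeds; the transition-recovery
check requires max-entry error < 0.03 on rows with ≥ 200 observed
exits at n = 5 000. The default analysis cohort is 446 patients, the
published registry size.

## Known limitations

Estimated transition rows are conditional on the observation window:
multi-site first relapses dilute the breast row relative to the
configured single-draw probabilities (0.30 observed vs 0.35
configured at the defaults), and truncation removes late transitions.
The estimator targets the embedded jump chain, not a continuous-time
intensity model; no uncertainty is attached to a_ij (a Bayesian or
bootstrap layer would be the natural extension). The spreader/sponge
factor depends on the chosen mass definition near factor ≈ 1 — sites
close to neutral can flip between the two modes — which is exactly why
both are exposed.
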