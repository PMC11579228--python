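# Methods

## The task and its data

A phase adjustment task (PAT) session consists of a 2-minute baseline
heartbeat recording followed by 2 practice and nominally 20 main trials.
On each trial, tones triggered by the participant's heartbeat are played
at a delay; the participant turns a dial through a sequence of candidate
delays and confirms one, then rates confidence on a 0–9 scale. The
screener is the structurally identical control task in which the
participant matches two external tones. Sessions are stored in the
`pat-session/1` JSON dialect defined by this package (JSON Schema in
`src/patkit/schemas/`): timestamps in milliseconds from session/trial
start, durations in seconds, unknown fields preserved in a metadata map.
Sessions may record both within-trial beat timestamps and discrete
heart-rate samples, so the engagement filter can be interpreted on either
signal; the filter operates on the sample count.

## Quality control

Main trials are removed when the dial trace is empty (the participant
never engaged the dial) or when fewer than 5 heart-rate samples were
recorded. Participants with fewer than 17 valid main trials are excluded;
the rest keep their first 17 valid trials in presentation order so all
scored participants contribute equal trial counts. Both thresholds are
configurable (`QCConfig`); the matched analyses additionally require at
least 18 valid trials as an inclusion rule while still scoring 17.
Whether "17 valid trials" should be counted within some prefix or in
total is ambiguous; the total is used. Participants reporting more than
20 main trials (an app malfunction) and participants missing sex or age
are excluded outright. With multiple completions, the first completion
providing 17 valid trials is used.

## Consistency score

Each trial's confirmed delay is reduced to a phase angle on the cardiac
cycle, θ = 2π·((delay mod IBI)/IBI), using the trial's own mean
inter-beat interval by default (`scoring.ibi_source = "baseline"`
switches to the baseline mean; with a steady heart the two coincide).
The participant's score is the circular mean resultant length of the 17
angles, R = |Σ e^{iθ}|/n: exactly 1 when all angles coincide, with
expectation √π/(2√n) ≈ 0.215 under uniform scatter at n = 17 (R is a
positively biased null statistic, not mean-zero). R is rotation- and
permutation-invariant, so delay *preferences* do not affect it — only
their spread does. A pairwise angular-similarity alternative (mean over
pairs of 1 − d(θᵢ,θⱼ)/π, rescaled from its uniform expectation 1/2 to
[0, 1]) is provided for sensitivity analysis; the exact formula used by
the original PAT software is not public, and whether its 0.42 screener
threshold lies on the same numeric scale as R cannot be confirmed —
reports therefore record the scoring method used. The screener pass rule
is score > 0.42, strict.

## Mixture classification

Cohort scores are modelled as a two-component univariate Gaussian
mixture fitted by EM. Initialization: one deterministic start (means at
the 25th/75th percentiles, equal weights, SDs at half the pooled SD)
plus 10 seeded random restarts (means drawn from the data); the best
final log-likelihood wins, making fits reproducible bit-for-bit given
scores, seed and config. Convergence: absolute log-likelihood change
< 1e-8, max 1000 iterations; component SDs are floored at 1e-3 to
prevent collapse on a bounded score; identical scores raise a degeneracy
error. The higher-mean component is labelled interoceptive.

Belonging probabilities are derived from per-component z-scores,
z_k = (score − μ_k)/σ_k, as two-sided normal tails P(|Z| ≥ |z_k|) — the
probability statements are about the z-scores, not posterior
responsibilities; a posterior alternative including the mixture weights
is selectable (`belonging.method = "posterior"`) because either reading
of the upstream convention is defensible, and reports name the method
used. The Bayes factor is the larger belonging probability over the
smaller (clamped at 1e-300), and labels are assigned at BF strictly
greater than 3 / 10 / 30, else unclassified. Labels are nested by
construction: classification at a stricter threshold implies the same
label at all looser ones. The mixture is refit within each analysis
sample by default (`refit_per_sample`), since pooling across differently
filtered samples changes the score distribution; a frozen fit can be
applied instead when classifying degenerate cohorts (used in the
ground-truth recovery tests).

## Cardiac and engagement metrics

RR intervals are successive differences of the baseline beat
timestamps. Resting HR = 60000/mean(RR); SDNN is the sample SD
(ddof = 1); RMSSD the root-mean-square of successive differences; pNN50
the percentage of successive-difference magnitudes strictly above 50 ms
with denominator the number of successive pairs. No artifact correction
is applied by default (an optional RR-range filter exists). Engagement
per participant: total and mean time over the 17 selected trials, mean
dial turns (raw trace length by default; a config switch counts unique
positions), and the total number of valid trials.

## Statistics battery

Group comparisons follow fixed conventions validated against the pooled
study's printed tables: Student pooled-variance t (df = n₁+n₂−2, matching
the printed df of 264 for 266 participants); Pearson χ² with all-zero
rows/columns dropped before computing X² and df — required because the
non-interoceptive column is empty at BF30, where the printed statistics
behave as df = 1 — and *no* continuity correction (all 12 printed χ²
values reproduce to 3 decimals under these two choices, which is how
they were verified); Mann-Whitney rank-sum with tie-corrected normal
approximation reporting |Z| (continuity correction off by default,
available by flag); Spearman's ρ on mid-ranks; OLS residualization of
consistency on covariates (resting HR and pNN50, then also age) followed
by a pooled t on the residuals; one-way ANOVA; and analytic power of the
two-sided pooled t via the noncentral t with ncp = d·√(n₁n₂/(n₁+n₂)).
All p-values are two-tailed; no multiple-testing correction is applied.

The four analysis samples are declarative predicate lists: full (no
filter); full_matched (≥18 valid trials, drop females aged 18);
screened (screener completed and passed > 0.42); screened_matched
(screened plus the same matching rule — the original age-matching rule
for this sample is not fully specified, so the shipped predicate is a
documented stand-in and user-configurable).

## Synthetic cohorts

The generator emulates the pooled study's structure: 266 participants,
163 female, ages ~N(27.3, 10) clipped to 18–60, four datasets in the
published proportions with screener sessions in datasets 1–2.
Interoceptive status is Bernoulli per sex (0.55 female / 0.35 male by
default — the sex effect is injected through prevalence rather than
concentration, since score data cannot distinguish the two mechanisms; a
concentration channel is available). Interoceptive participants draw
trial phases from a von Mises around a personal preferred phase with
κ = 1.2, chosen so the mean resultant length at 17 trials ≈ 0.54,
matching the interoceptive component mean; non-interoceptive
participants draw uniform phases. Inter-beat intervals follow a
participant-level mean (790/760 ms male/female, between-subject SD
90 ms → resting HR ≈ 76/79 bpm) with within-subject AR(1) dynamics
(coefficient 0.2) targeting SDNN of 52/58 ms, which puts pNN50 near
45/53%. Observed HRV in the motivating study is several-fold larger
(SDNN ≈ 172 ms), implausibly so for 2-minute recordings without stated
preprocessing, and is deliberately not matched. Confidence is a rounded
clipped latent normal with means 5.5 (male) / 4.6 (female), SD 2; trial
durations are lognormal (median 20 s); dial turns Poisson(27).

QC failures are injected at the participant level, mutually exclusively:
with default probabilities 0.15 / 0.01 / 0.015 a participant gets 4–8
invalid trials (guaranteeing exclusion), extra main trials, or a missing
demographics row. Unaffected participants get at most 3 naturally
invalid trials (Poisson 0.9, capped), so they always retain ≥17 valid
trials — injected counts therefore equal exclusion-ledger counts
exactly, which the bookkeeping tests assert.

`simulate_scores` is a score-level shortcut drawing consistency scores
directly from the assumed Gaussian components (means 0.22/0.55, SDs
0.07/0.12, clipped to [0, 1]). It is used where only the score
distribution matters — mixture-parameter recovery over 100 replicate
cohorts and t-test calibration over 1000 — keeping those studies to
seconds rather than hours. Problem sizes in the tests and the acceptance
script (100 recovery cohorts, 1000 null replicates, one 300-participant
full-session cohort, 10⁵ Monte-Carlo draws) were chosen as the smallest
sizes at which the checked tolerances are statistically meaningful.

What passing tests show — and what they do not: the synthetic cohorts
share the study's *statistical* structure (bimodal scores, sex-linked
prevalence and confidence shifts, realistic attrition), so they validate
the pipeline's correctness, calibration and bookkeeping. They do not
contain photoplethysmography noise, pulse-transit-time offsets,
non-stationary heart rhythms, or behavioral idiosyncrasies of real dial
use, and the study's raw data are not deposited — so group means, t
statistics and classification tables computed on synthetic cohorts are
scale-realistic but not reproductions. The quantities that *are* exactly
checkable against print are the contingency-table statistics and the
power claim.

## Known limitations

- The original consistency formula and the provenance of the 0.42
  screener threshold are not public; mean resultant length is the
  canonical statistic with the described behavior, but absolute score
  scales may differ from the original software.
- pNN50's 50 ms threshold makes it sensitive to the unmodelled
  measurement noise of optical heart-rate sensing.
- The EM fit assumes exactly two Gaussian components on a bounded
  score; no model selection over component count is performed.
- Belonging probabilities via two-sided tails are not posterior
  probabilities; Bayes factors computed from them should be read as the
  evidence convention of this task family, not as Bayesian posterior
  odds.
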