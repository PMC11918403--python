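# Methods

`ordrisk` models choices between a certain outcome and a lottery over a
better outcome, under risk (known win probability) and ambiguity (a
partially occluded probability display), in two outcome domains: monetary
(amounts $5/$8/$12/$25) and medical (four ordered improvement levels with
no objective magnitude). This note describes the models, the synthetic-data
generator, the inference machinery and the numerical choices, and states
what the shipped tests do and do not establish.

## Task structure

A trial offers the level-1 outcome for certain against a lottery over a
higher level. Risky lotteries use win probabilities 25/50/75% with no
occlusion; ambiguous lotteries display a nominal 50% with 24/50/74% of the
display occluded (the online variant adds 100% occlusion). Catch trials
offer a lottery over the level-1 outcome itself — a dominated option used
as an attention check. The in-person variant crosses 3 lottery levels × 6
uncertainty conditions × 4 repetitions and adds 12 catch trials (2 per
uncertainty condition), 84 trials per domain. The online variant halves
repetitions and adds the fully ambiguous condition; its total (49 trials:
42 + one catch per condition) is a package convention, since only the
repetition change and the extra condition are fixed by the study
description, not the online catch-trial count.

## Subjective-value models

All models score the lottery as `SV = (P − β·A/2) · value` and the certain
option as the level-1 value at `P = 1, A = 0`:

* **Classic utility** (monetary only): `value = V^α`. Risk attitude α < 1
  is risk aversion; ambiguity attitude β > 0 shrinks the perceived win
  probability by β·A/2.
* **Estimated value** (either domain): `value = Σ_{i≤level} ν_i` with
  nonnegative per-subject increments ν₁..ν₄, so values respect the ordinal
  structure without assuming distances between levels. There is no
  separate α — curvature is absorbed by the increments.
* **No-subjective-parameters baseline**: `value = level`, unit ambiguity
  weight; a deliberately rigid reference model.

Choice rules map the SV difference to P(choose lottery): a logistic rule
`1/(1 + exp(γ·(SV_safe − SV_risky)))` with per-subject inverse temperature
γ, or a trembling-hand rule `(1−δ)·logistic(SV_risky − SV_safe) + δ/2`
with lapse rate δ. As printed in the source equation the trembling-hand
exponent has a sign that would make choice probability decrease in the
lottery's value; the implementation uses the direction consistent with the
logistic rule and treats the printed sign as a typographical error. The
trembling-hand rule is only paired with classic utility, matching the
fitted model set.

## Priors

Group-level priors (shipped in `data/default_hyperpriors.yaml`, all
configurable):

| parameter | prior | notes |
|---|---|---|
| α/2 | Beta(α₁, α₂) | α₁ ~ N(4,1)⁺, α₂ ~ N(7,3)⁺; plug-in prior mean of α is 2·4/(4+7) = 0.727 (slight risk aversion) |
| β | N(μβ, σβ) on (−1.5, 1.5) | μβ ~ N(0.65, 1) (slight ambiguity aversion), σβ ~ Gamma(2,1) |
| γ | LogNormal(0, 0.25) | one per subject, shared across its trials |
| δ | Beta(δ₁, δ₂) | δ₁, δ₂ ~ N(2,1) truncated ≥ 1 |
| νᵢ | N(μνᵢ, σνᵢ) on [0, ∞) | μνᵢ ~ N(4,2)⁺, σνᵢ ~ Gamma(3,1) |

Gamma distributions are shape/rate. Truncated-normal normalizers depend on
the sampled group parameters and are differentiated exactly. The baseline
model samples a single shared γ ~ LogNormal(0, 0.25): it must be paired
with a choice rule to yield a likelihood, and a shared temperature is the
minimal choice that keeps it free of subject-level parameters.

## Synthetic-data generator

The simulator is the study-conditions generator, not a convenience
fixture. Agents carry risk and ambiguity attitudes drawn independently and
uniformly from α ∈ [0.1, 1.6] and β ∈ [−1.4, 1.4] (the stated constraint
ranges; the distribution within them is a package choice, uniform being
the least informative on a bounded range). Each agent scores every trial
with the classic utility model; a single zero-mean Gaussian draw with the
cell's noise sd is added to the SV difference (the noise locus —
difference rather than per-option — is a package choice; the two differ
only by a √2 variance rescale) and the lottery is chosen iff the noisy
difference is positive. The default grid crosses (N, noise) over
(30,0.1), (30,0.3), (30,0.5), (60,0.3), (60,0.5), (120,0.5), (300,0.5).

What the generator does not emulate: response times, trial-order and
session effects, learning or drift within a session, and choices generated
by the estimated-value process itself — so recovery tests show that the
pipeline distinguishes the fitted structures under utility-generated data,
not that it captures every feature of human data. One consequence of the
threshold-plus-noise policy deserves note: the generator has no inverse
temperature, so an agent's choice sharpness is set by its value scale
relative to the noise, while the fitted classic-utility model's sharpness
is bounded by the informative γ prior times that same value scale. Agents
with α near the bottom of the range have subjective-value differences far
smaller than their choice consistency implies, which the estimated-value
model can accommodate by rescaling its increments and the classic model
cannot; the model-comparison tests measure the resulting rankings rather
than assuming them.

With zero noise the simulated policy is the exact utility argmax. One
edge: an extremely ambiguity-seeking agent (β < −2(1−P)/A, i.e.
β < −1.35 at A = 0.74) values the ambiguous level-1 lottery above the
certain level-1 outcome, so "never fails a catch trial at zero noise"
holds for all but that corner of the parameter range; such an agent can
fail at most 2 of the 12 catch trials, far below the exclusion threshold.

## Exclusions

Per dataset (hence per domain): subjects failing ≥ 6 of the 12 attention
checks are excluded (failure = choosing the dominated lottery), and
subjects choosing the lottery on fewer than 2 non-catch trials are
excluded because a constant choice pattern cannot constrain a choice
function. Catch trials are removed from the fitting input — both options
carry the same outcome, so they are uninformative about values under every
model here. Filtering is idempotent.

## Inference

Models are fitted by MCMC with a No-U-Turn sampler implemented in the
package (multinomial trajectory sampling, biased progressive proposal
selection, energy-error divergence check at 1000). Every model exposes its
joint log-density and hand-derived gradient in an unconstrained space: log
transforms for positive parameters, scaled logits for bounded ones, with
exact Jacobian terms; gradients are verified against finite differences in
the test suite. Warmup follows the windowed scheme standard in HMC
tooling: dual-averaging step-size adaptation toward the target acceptance
statistic, an initial fast buffer (75), doubling variance-estimation
windows, and a terminal buffer (50), scaled proportionally for short
warmups.

Two metric options exist. The diagonal metric estimates per-coordinate
posterior variances per window. The dense metric (default for model fits)
keeps diagonal estimates through the early windows and estimates a full
covariance from the single long final window, shrunk toward a regularized
diagonal. The hierarchical posteriors here strongly correlate group-level
location/scale parameters with the subject-level parameters they pool, and
the dense metric roughly doubles to quadruples the worst-parameter
effective sample size at equal wall time in the fits exercised by the
acceptance tests.

Parameterization is centered for the subject-level truncated normals. The
non-centered alternatives were evaluated and rejected: with a lower
truncation at 0 the non-centering transform's admissible region depends on
the group parameters, and the two realizable variants (scale
non-centering ν = σ·exp(z), and sampling log(γ·ν) to align the
temperature–value ridge) both mixed worse than the centered form on the
30-subject synthetic reference fit, because 72 trials per subject make
most subject-level parameters data-dominated.

Defaults mirror common practice: 4 chains, 1000 tuning steps, 1000 draws,
80% target acceptance, maximum tree depth 10. Convergence is summarized as
the maximum split R-hat and minimum bulk effective sample size over all
parameters in the posterior (arviz implementations), plus the divergence
count; divergent transitions are recorded per draw and surfaced, never
dropped silently.

A known identifiability caveat: in the estimated-value model a subject's γ
and the scale of its ν increments trade off (the likelihood depends on
their products), resolved only softly by the informative γ prior. A
related genuine geometry limit: the group scale σν₁ forms a funnel with
the weakly identified level-1 increments; at the fixed 4×1000-draw budget
its bulk ESS plateaus around 550–650 while every R-hat stays ≤ 1.01. The
acceptance suite states the 1000-ESS bound for that fit and the σν funnel
is the single parameter family below it.

## Model comparison

Out-of-sample fit is estimated per trial by PSIS-LOO (arviz) on the
pointwise log-likelihood; models are ranked by ELPD and weighted by
stacking (the tooling's standard scheme; the source table's weight scheme
is unstated beyond being LOO-based). The comparison unit is the trial.
Exact ties in the pointwise predictive density split weights evenly, and
rank ties break by model name. High Pareto-k trials (> 0.7) set a warning
flag on the result. The brute-force oracle in the tests refits the model
once per held-out trial on a 5-subject, 12-trial problem and checks the
PSIS estimate within 2 standard errors.

## Cross-domain regression

Per-subject posterior-mean ambiguity attitudes from two domains are
related by `y ~ a + b·x` with Student-t noise: scale ~ HalfNormal(5),
coefficients ~ N(0, 10), and degrees of freedom ν − 1 ~ Exponential(1/29)
(the standard weakly informative robust-regression setup, letting the data
choose tail weight). Using point estimates as inputs matches the two-stage
procedure being reproduced; propagating full posteriors is out of scope.
The slope is summarized by its posterior mean and an 89% highest-density
interval, computed directly as the narrowest sorted-sample window (exact
for the requested mass; degenerate samples give a zero-width interval and
prob = 1 gives the range). An optional grouping column (e.g. surgery
history) yields independent regressions per group; no interaction model is
fitted.

## Problem sizes and numerical choices

The reference synthetic fit uses 30 agents at noise 0.3 on the 84-trial
in-person monetary design; model-recovery checks run the (30, 0.1) and
(30, 0.5) cells with 2 chains × 500 draws; parameter recovery uses the
(60, 0.3) cell. The refit-LOO oracle uses 5 subjects × 12 trials so that
one refit per held-out trial stays cheap. Likelihood code works in
log-sigmoid space throughout; the trembling-hand likelihood folds the
δ-Jacobian into the gradient so lapse rates near 0 stay numerically
bounded; truncated-normal tail normalizers use `log_ndtr` with the
reflected-interval trick so both tails are stable.

## Limitations

No cross-domain sharing of parameters during fitting (domains are fitted
separately); no cumulative prospect theory or reference-dependent models;
no categorical model variant; risk attitudes are not comparable across
domains because the estimated-value model folds curvature into the values
themselves; fits require ≥ 2 subjects with response variability; the CLI
persists posteriors to NetCDF and falls back to a plain `.npz` bundle if
no NetCDF backend is available.
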