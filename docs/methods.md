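# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices and the known limitations of `mbdim`.

## Task model

Each trial: a binary first-stage choice; a probabilistic transition
(`p_common = 0.7`) to one of two second-stage states under the fixed
mapping choice 0 → state 0; a binary second-stage choice rewarded with
the current probability of that state–choice pair. The four reward
probabilities evolve as independent Gaussian random walks with per-trial
step SD 0.025 (a task-lineage convention; the value is exposed in
`TaskConfig`), constrained to (0.25, 0.75). Steps that would leave the
bounds are *reflected* by default — reflection preserves the local
symmetry of the increment distribution near a boundary better than
truncation, which piles mass onto the bound; truncation is available via
`boundary="truncate"`. Initial probabilities are uniform within the
bounds. Screen-side counterbalancing and reaction-time generation are
not modeled; simulated RTs are cosmetic lognormal draws used only to
exercise the quality-control rules.

## Hybrid agent

State–action values use the rescaled parameterization in which the
learning-rate factor is omitted from every innovation term
(`Q ← (1−α)Q + target`), equivalent to scaling the Qs and their softmax
weights by α. Stage-2 chosen values update toward the reward; stage-1
model-free values update by TD(0) (toward the stage-2 value) and TD(1)
(toward the reward) in parallel; model-based values take the maximum
stage-2 value of the state each choice predominantly produces; all
unchosen/unvisited values decay by (1−α) at trial end. Splitting the
model-free weight into β_MF0/β_MF1 removes the eligibility-trace
parameter; the aggregate weight is reconstructed post hoc as
`β_MF = β_MF0 + α β_MF1`.

Two deliberate resolutions of ambiguities, both switchable:

- The TD(0) target uses the stage-2 value *after* that trial's stage-2
  update (the update equations apply in listing order);
  `mf0_uses_updated_stage2=False` uses the pre-update value.
- Q values initialize at 0 (neutral under a softmax over value
  *differences*); `q_init` exposes alternatives such as 0.5.

## Hierarchical EM

Per-subject parameters are estimated on a transformed scale (α via
log-odds, weights untransformed) under a diagonal Gaussian group prior.
E-step: MAP by L-BFGS with analytic gradients (the likelihood gradient
propagates dQ/dα through the update recursions), 5 restarts per subject
with perturbations drawn once so repeated E-steps are deterministic;
Laplace covariance from a central finite-difference Hessian (step 1e-4),
with posterior variances clipped at the prior variance. M-step: prior
mean from the MAP estimates, prior variance from MAP second moments plus
the Laplace variances. Convergence: maximum prior-mean shift < 1e-4
(default cap 100 iterations; non-convergence returns the best fit with a
warning). `no_pooling=True` removes the prior, giving per-subject ML.

Calibration caveat, measured by the acceptance suite: at 200-trial
sessions the likelihood carries a ridge `β_MF0 + α β_MF1 ≈ const`, and
the converged group means for α and the MF0/MF1 split are biased by
roughly 0.03–0.1 (transformed units) even though the EM verifiably
maximizes its Laplace objective — the quantities the analysis interprets
(β_MB, reconstructed β_MF, and their subject ranking) recover well
(β_MB truth correlation r ≈ 0.7–0.87). The bias vanishes with longer
sessions (~1,500 trials).

## Stay regression

Per-subject Newton/IRLS logistic fits of stay (stage-1 repeat) on
previous Reward (±1), Transition (±1) and their product; quasi-separated
fits are flagged and refit with an L2 penalty (0.5). The group model
regresses each within-subject coefficient on an intercept, z-scored
score and continuous covariates, and gender coded −1/+1 (so main effects
are evaluated at the gender midpoint). This two-stage estimator is the
default engine: its stage-2 inference is exactly calibrated (t-based
OLS/WLS on independent per-subject summaries — the acceptance suite
verifies ~5% type-I error for the Score × Reward × Transition test) and
it scales to thousands of subjects. A Laplace-type penalized GLMM with
random intercept, Reward, Transition and Reward × Transition per subject
(diagonal covariance) is available as `engine="glmm"`; the two engines
agree in sign and to within ~35% in magnitude on well-powered synthetic
data, with the two-stage estimate slightly attenuated toward zero by
per-subject estimation noise.

The percent-change index is
`100 × β(Score × Reward × Transition) / β(Reward × Transition)` — the
moderation expressed relative to the group-mean model-based effect. An
alternative marginal-probability definition would give similar values at
these effect sizes; the ratio form is fixed because it reproduces the
reported narrative arithmetic (e.g. −0.040 / 0.286 ≈ −14%).

## Quality control

Criteria apply sequentially to the surviving sample, one reason per
subject: >10% missed trials; >95% same-key presses among registered
responses (both stages pooled — key identity equals choice identity
because screen sides are not modeled); mean RT beyond ±2 SD of the
sample of subject means (the written two-sided rule; a fast-only switch
matches the "implausibly fast" intent; median and all-sample variants
exposed); failed catch item; zero IQ answers correct.

## Psychometrics

The item correlation matrix mixes Pearson (numeric–numeric), polyserial
(numeric–binary) and polychoric (binary–binary) coefficients, matching
the treatment of ordinal scales as numeric except for the binary
schizotypy items. Polychoric/polyserial estimation is two-step ML:
thresholds from the margins, then a bounded 1-D likelihood maximization
over ρ using a Gauss–Legendre evaluation of the bivariate-normal CDF
(absolute accuracy better than 1e-6; test tolerance ±0.01 against
grid-search oracles). The pairwise-mixed matrix is usually slightly
indefinite and is eigenvalue-clipped to the nearest PSD matrix with unit
diagonal (flagged).

Factor extraction is maximum likelihood (statsmodels) with uniquenesses
floored at 0.005 under Heywood cases (flagged); rotation is
gradient-projection oblimin with γ = 0 (quartimin) to 1e-6, columns
sign-fixed so each factor's largest-|loading| item loads positively.
Factor count: the CNG scree statistic fits least-squares slopes to
eigenvalue triples i..i+2 and i+3..i+5 and returns the position of the
greatest slope change (k = argmax + 3 in 0-based indexing; at least 6
eigenvalues required); Horn's parallel analysis (95th percentile of
column-permuted eigenvalues, 500 replicates) is provided as a
comparator. Scores are Thurstone regression scores
`Z R⁻¹ (Λ Φ)`, z-scored (Bartlett available). Loading summaries report
per-questionnaire means (SDs) per factor, flagging means strictly
greater than 0.25 as dominant.

## Item selection

The outcome is the per-subject Reward × Transition coefficient
residualized on age, IQ and gender; items are z-scored. The solver is
coordinate-descent elastic net (scikit-learn) under the objective
`½‖y − Xβ‖²/n + λ(α‖β‖₁ + (1−α)‖β‖₂²/2)`, with the λ-grid
log-spaced (1e-4..1) and the α-grid linear (0.01..1). Nested CV tunes
(α, λ) by mean inner-fold MSE; models carry no intercept because the
inputs are globally centered — a per-fold intercept would leak the
training-fold mean into the held-out correlation and bias the null
distribution negative. An item is "selected" in an iteration when its
coefficient is nonzero in the majority of the 10 outer-fold models
(`aggregation="all"` requires all folds); retention requires selection
in ≥95% of the 100 iterations.

## Adaptive IQ test

2PL items (`P = 1/(1+e^{−a(θ−b)})`, information `a²P(1−P)`). The
synthetic 26-item bank draws discriminations lognormal with log-mean 0
and log-variance 0.3 and difficulties N(0,1), emulating a screened
progressive-matrices-style bank. The fixed starter is the most
informative item at θ = 0 and contributes no likelihood term; each of
the 5 scored steps samples uniformly among the top-3 unadministered
items by information at the current estimate and rescores θ by Newton
posterior mode under a standard-normal prior (grid fallback on
non-concavity). Across synthetic banks the 5-item estimate correlates
r ≈ 0.71–0.80 with full-bank scores; the correlation varies with the
bank draw, so the test suite asserts the ensemble average.

## Synthetic population

Defaults define the study conditions: 1,413 subjects; ages ~N(33, 11)
clipped to 18–76; 58% female (gender −1/+1); IQ as a latent N(0,1)
trait measured by the adaptive test. Three oblique factors with
correlations 0.35/0.30/0.25 (plausible mid-range values; the source
tables do not print factor correlations). The 209 analysis items split
over nine instruments by their published lengths (OCD 18, depression 20,
trait anxiety 20, alcohol 10, apathy 18, eating 26, impulsivity 30,
schizotypy 43 binary, social anxiety 24) — an explicit assumption
recorded in the manifest — plus one catch item excluded from analysis.
Item loadings are drawn per item around per-questionnaire target
means/SDs that mirror the published loading table (trait anxiety, apathy
and depression dominating factor 1; OCD, eating and alcohol factor 2;
social anxiety factor 3); rows are rescaled if communality under the
oblique model would exceed 0.9. Responses come from a graded-threshold
model: latent `y* = λᵀf + √(1−h²) ε` cut at thresholds equally spaced
in [−1.2, 1.2] (binary items at 0). This stand-in generative model has
no counterpart in real questionnaire data — real acquiescence bias,
skewed endorsement rates and local item dependence are *not* emulated,
so passing tests certify the pipeline's statistical machinery, not its
robustness to those artifacts.

Hybrid parameters are drawn from a documented group prior (transformed
scale): α logit-normal around 0.5 (SD 0.5), β_stage2 1.2 (0.3), β_MB
0.7 (0.3), β_MF0 0.3 (0.2), β_MF1 0.5 (0.25), β_stick 0.15 (0.2); the
β_stage2 scale follows typical published two-step fits after the 1/α
rescaling of the Qs. The model-based weight is then set to
`β̄_MB (1 − 0.17 z_f2 − 0.05 z_age + 0.05 z_IQ + 0.04 gender) + ε`,
ε ~ N(0, 0.15), clipped at 0.01; β_MF1 scales with +4% per SD of age.
Noncompliance (trial missers, key mashers, fast responders, catch
failers, zero-IQ responders) is planted at configurable rates, default
zero.

## Problem sizes and verification

The test suite runs the full chain at documented sizes: walk/transition
checks at 10,000 trials; factor-number recovery at 800 subjects on a
~60-item battery and again at 1,400 × 209 in the acceptance script;
planted-effect recovery at 1,400 subjects × 200 trials; EM recovery at
300 × 200; type-I calibration over 200 null replicates of 120 subjects.
Across replicate seeds the recovered percent reduction is unbiased
(mean ≈ 17.4, SD ≈ 2.7 at n = 1,400) when moderated by the factor score
that drives the planted decline; moderating by battery-estimated factor
scores attenuates it by the score validity (~0.90), i.e. to ≈ 15.

## Known limitations

- The EM group means for α and the MF0/MF1 split are biased at 200-trial
  sessions (see above); interpret β_MB and β_MF.
- The polychoric/polyserial matrix is pairwise and needs PSD smoothing;
  a full-information estimator is out of scope.
- The GLMM engine materializes dense fixed-effect blocks and is
  practical to a few hundred subjects; the two-stage engine is the
  scalable default.
- Stability selection at the full 50 × 50 grid × 100 iterations is
  compute-heavy; tests exercise reduced grids, and the full
  configuration remains available through `EnetConfig`.
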