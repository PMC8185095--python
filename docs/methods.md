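# Methods notes

This note documents the model, the estimation machinery, the synthetic
cohort generator and every numerically consequential default, in the order a
reader would meet them in the pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task model

The environment is the canonical two-step task: two first-stage actions,
each leading to its "common" second-stage state with probability
`p_common = 0.70` and to the other state otherwise; two actions per
second-stage state; binary reward with probability given by one of four
independent random walks (one per second-stage stimulus). The walk dynamics
are **assumptions**, not reported values: Gaussian steps of s.d. 0.025 per
trial, reflected at [0.25, 0.75], following the convention of the original
version of the task. Both are configurable in `TaskConfig` and the
assumption is recorded in every pipeline manifest. Sessions are 200 trials;
practice trials are not modeled — agents start with all action values at 0.
The payout rule (a fraction of accumulated rewards) has no effect on
trial-level computation and is not modeled.

Stimulus indexing is fixed package-wide: action `a` leads commonly to state
`a` (A = 0, B = 1) and walk column `2*state + choice2` addresses the four
second-stage stimuli.

## Choice model

The hybrid learner combines SARSA(λ) model-free values with model-based
planning over the true transition matrix (participants in this design are
instructed about the transition structure, so the planner does not learn
it). The mixture weight ω and the perseveration bonus π act at the first
stage only; the second stage is a softmax over learned state–action values.
The pure model-free variant freezes ω = 0 (6 free parameters); the pure
model-based variant freezes ω = 1 and drops λ (5 free parameters). Whether
the original formulation carried perseveration at the second stage or value
decay cannot be settled from the available description; the canonical
formulation (neither) is used. α₁ stays free in the pure-MB variant even
though it cannot affect the likelihood there; its posterior simply reproduces
the prior, which the Laplace machinery handles (see below).

One likelihood code path serves both simulation and fitting: the replay
kernel (numba-compiled for speed) reproduces the agent-module dynamics
exactly, and a property test asserts that the probability of a simulated
trajectory under its generating parameters equals `exp(-nll)` of the replay
to 1e-8.

## Hierarchical estimation

Parameters are estimated on unconstrained scales — logit for α₁, α₂, λ, ω;
log for β₁, β₂; identity for π — with an independent Gaussian population
prior per dimension (diagonal covariance). The EM scheme is standard
empirical Bayes with Laplace approximation:

- **E-step**: per-subject MAP by multi-start L-BFGS-B on
  `nll(z) + Σ (z-μ)²/(2σ²)`; the first start is the prior mean, the rest are
  prior draws (first iteration: 10 starts by default; later iterations: the
  previous MAP as warm start plus 1 draw). Objective tolerance 1e-6.
  The posterior covariance is the inverse of a central-difference Hessian
  (step 1e-3), symmetrized and ridge-regularized (1e-6·I, escalating) if not
  positive definite.
- **M-step**: `μ_k = mean(z_k)`, `σ²_k = mean(z_k² + var_k) − μ_k²`, with a
  variance floor of 1e-6 (hit, by construction, when the cohort carries no
  between-subject variance in a dimension).
- **Convergence**: max |Δμ| and max |Δσ²| below 1e-3, at most 100
  iterations. Initial prior: μ = 0 on logit/identity dimensions, 1.0 on log
  dimensions (temperatures near e), σ² = 2.25.

Model comparison uses the integrated BIC,
`iBIC = −2 Σ_i log p̂(data_i | prior) + 2d·log N`, where `log p̂` is the
subject-level Laplace marginal at the MAP, `d` is the number of free
parameters (each contributing a mean and a variance hyperparameter) and `N`
counts **choices** (two per trial). Counting trials instead is supported via
`integrated_bic(result, total_observations=...)`; the choice-based default
is recorded in the manifest. Group comparisons use back-transformed
(natural-scale) ω̂, matching nonparametric tests on the weight itself.

Transformed coordinates are clipped at ±30 before back-transform — far
outside any plausible optimum, purely an overflow guard.

## Behavioral statistics

*Stay/switch analysis.* Effect coding ±1 (previous outcome: reward +1;
previous transition: common +1), so a pure model-free learner loads on the
outcome main effect and a pure model-based learner on the outcome ×
transition interaction. The estimator is a **two-stage summary-statistics
scheme**: per-subject logistic regression with a small ridge penalty (1e-3,
guarding complete separation), then grand-mean t-tests and OLS group
contrasts (HC reference, plus an OCD−SIB recode pass) on the per-subject
coefficients. A frequentist logistic GLMM is not available in the Python
stack this package builds on; the term structure and effect directions — not
a particular mixed-model estimator — are the analysis contract, and the
per-subject coefficients double as the subject-level "outcome" and
"interaction" metrics used in the correlation matrix.

*RT analysis.* The second-stage RT model is a linear mixed model
(statsmodels `MixedLM`, random intercept + transition slope per subject) of
RT on a common-transition indicator crossed with group, so the transition
coefficient is the common-minus-rare difference in ms (negative when rare
transitions slow responding). A two-stage fallback (per-subject rare/common
difference, then group-level OLS) is used when the mixed fit degenerates.
The per-subject RT effect is mean(rare) − mean(common) of valid
(positive, non-missing) second-stage RTs; no outlier trimming is applied.

## Group inference

The Jonckheere–Terpstra statistic counts, over ordered group pairs,
`#(x_i < x_j) + ½·#(x_i = x_j)`. The p-value is one-sided for the stated
ordering by unstratified label permutation with the add-one convention
`p = (1 + #{J* ≥ J}) / (1 + n_perm)` (a valid permutation p that is never
exactly 0); an exhaustive-enumeration mode exists for tiny groups and is
used as the Monte-Carlo oracle in tests. 10,000 permutations by default.
Post-hoc pairwise comparisons are Wilcoxon rank-sum tests (exact null
distribution for small tie-free samples, tie-corrected normal approximation
otherwise), uncorrected, as is conventional for this design's post-hocs.

The robustness arms residualize the tested values on (a) age and (b) the
cognitive scores (DSST, digit-span backwards) by OLS before re-testing;
gender enters residualization/partial correlations as a binary indicator.
Partial correlations are computed directly (residualize both variables,
correlate, t-distribution p with n−k−2 df; ranks first for Spearman) and are
cross-checked in the test suite against an independent implementation
(pingouin).

## ROI analysis

Subcortical volumes arrive as a plain table in mm³; extraction from imaging
is upstream and out of scope. Volumes are divided by the subject's
intracranial volume (display scale ×10,000 by convention). Correlations with
the RT effect are Spearman, overall and per group, for bilateral putamen and
caudate; a covariate-adjusted mode (Spearman partial correlation given age
and gender) is exposed because designs of this kind use both conventions.

## Synthetic cohort generator

No subject-level data from the motivating design are publicly available, so
the generator is the package's reference input. Its defaults encode the
study structure:

| quantity | default | provenance |
|---|---|---|
| group sizes | HC 31 / SIB 27 / OCD 32 | study design |
| ω group means | 0.55 / 0.45 / 0.35 (HC/SIB/OCD) | plausibility choice with the study's ordering; *not* estimates |
| other parameter means | α₁ = α₂ = λ = 0.5, β₁ = β₂ = 4, π = 0.2 | typical fitted values for this task family |
| between-subject s.d. | 0.5 (transformed scale, all dims) | moderate heterogeneity; makes the ordered ω means detectable at design size in ≥95% of seeds |
| RT base | 830 ± 150 ms between subjects, trial noise 300 ms | group-level RT summaries of the design |
| rare-transition penalty | HC 71 / SIB 106 / OCD 46 ms | group mean rare−common differences |
| ICV | N(1.5e6, 1.5e5) mm³ | published norms |
| ROI ratios | putamen ≈ 5000/ICV, caudate ≈ 3500/ICV with sds 3.3e-4 / 2.4e-4 | published norms |
| volume–RT-effect coupling | HC +0.35, SIB −0.55, OCD −0.45 | signs from the design; magnitudes are a-priori plausibility choices |
| covariates | age ≈ 32 ± 10; DSST 57.7/50.2/42.1 ± 16; DS 6.7/5.3/5.6 ± 2.3; P(female) 0.55 | cohort table |

RTs are generated *independently of the agent's internal state* — an
additive penalty on rare transitions plus Gaussian noise (floored at
100 ms) — because the RT effect is treated as a separate model-based
signature. The optional `omega_coupled` mode scales each subject's penalty
by their generative ω (preserving the group mean), inducing the positive
RT-effect–ω correlation observed in such cohorts; the acceptance script
switches it on. Volume couplings act on the *normalized* ratios through a
Gaussian copula on the within-group ranks of the realized RT effect, so the
per-group correlation signs hold by construction regardless of session
noise; raw volumes are ratio × ICV.

What the generator does **not** emulate: RT distributions' skew (optional
lognormal mode exists but the default is truncated normal), symptom-severity
structure, missing-data mechanisms, medication effects, or any dependence of
choice behavior on covariates beyond the optional DSST→ω slope used for
confound-robustness tests. Passing tests on these cohorts therefore
demonstrate that the *pipeline* recovers injected structure of the study's
shape — not that real data would show that structure.

The `null_cohort` variant zeroes every group difference and coupling and is
the type-I-error calibration target.

## Problem sizes in the test suite and acceptance script

Simulation-based checks run at sizes chosen for a single CPU: parameter
recovery at the full design size (90 subjects × 200 trials, EM with 6/2
optimizer starts and ≤40 iterations); model recovery at 16 subjects ×
120 trials × 5 seeds with 3/1 starts and ≤6 iterations; JT calibration at
500 replicates × 2,000 permutations; power and sign-recovery sweeps at 20
seeds. The acceptance script fits all three models to the 90-subject cohort
with 4/1 starts and ≤25 iterations. All sweeps are seed-deterministic.

## Known limitations

- The per-subject Hessian is numerical; for nearly flat dimensions (e.g. λ
  at 200 trials) the Laplace variance is prior-dominated, which is the
  intended empirical-Bayes behavior but means σ² for such dimensions should
  not be over-interpreted.
- EM maximizes an approximate marginal; the monotonicity of the true
  marginal across iterations holds only up to Laplace and optimizer error.
- The two-stage stay estimator is consistent but less efficient than a full
  GLMM; its grand-mean tests treat subjects as exchangeable across groups
  under the null of no group effect.
- `wilcoxon_ranksum` falls back to the tie-corrected normal approximation
  whenever samples exceed 8 observations or contain ties.
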