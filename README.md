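# twostep

Analysis toolkit for the **two-step sequential decision task**, the standard
behavioral assay for separating *model-based* (goal-directed, prospective)
from *model-free* (habitual, reward-chasing) control. The package targets
clinical-cognitive study designs in which three groups — patients with
obsessive–compulsive disorder (OCD), their unaffected siblings (SIB) and
healthy controls (HC) — are compared on the balance between the two
controllers, asking whether reduced model-based control behaves like an
endophenotype (present, attenuated, in unaffected relatives).

It provides, as importable modules and a thin CLI:

- **Task simulation** (`twostep.task`): a binary first-stage choice leads to
  one of two second-stage states through fixed 70/30 transition
  probabilities; second-stage choices are rewarded with probabilities that
  drift as bounded Gaussian random walks (s.d. 0.025, reflected at
  [0.25, 0.75]); 200 trials per session by default.
- **Generative agents** (`twostep.agents`): the seven-parameter hybrid
  learner and its pure model-free / model-based special cases.
- **Model fitting** (`twostep.model`, `twostep.likelihood`, `twostep.em`):
  per-subject MAP estimation under a Gaussian population prior, hierarchical
  empirical-Bayes EM across subjects, Laplace marginal likelihoods and iBIC
  model comparison, wrapped statsmodels-style in `TwoStepModel.fit()` →
  `TwoStepResults.summary()`.
- **Behavioral statistics** (`twostep.behavior`): stay/switch regression
  (outcome × transition × group), the second-stage RT analysis (slowing
  after rare transitions as a second model-based signature), per-subject
  metrics and their Spearman correlation matrix.
- **Group inference** (`twostep.inference`): Jonckheere–Terpstra permutation
  test for ordered group differences, Wilcoxon post-hocs, covariate
  residualization and partial correlations.
- **Brain–behavior correlations** (`twostep.neuro`): ICV normalization of
  subcortical volumes and overall/per-group correlations with the RT effect.
- **Synthetic cohorts** (`twostep.cohort`): a generator that emulates the
  full statistical structure of such a study (ordered group means of the
  model-based weight, group-specific RT penalties, group-signed
  volume couplings), so every stage is testable without any subject data.

## The model

The model-free controller is SARSA(λ) over both stages. After a trial with
first-stage choice $a_1$, second-stage state/choice $(s_2, a_2)$ and reward
$r$:

$$\delta_1 = Q_2(s_2,a_2) - Q_{MF}(a_1), \qquad Q_{MF}(a_1) \mathrel{+}= \alpha_1\delta_1$$
$$\delta_2 = r - Q_2(s_2,a_2), \qquad Q_2(s_2,a_2) \mathrel{+}= \alpha_2\delta_2, \qquad Q_{MF}(a_1) \mathrel{+}= \alpha_1\lambda\,\delta_2$$

The model-based controller plans with the true transition structure:

$$Q_{MB}(a) = p\,\max_{a'}Q_2(S_a,a') + (1-p)\,\max_{a'}Q_2(S_{\bar a},a'), \qquad p = 0.7$$

First-stage choice is a softmax over the ω-weighted mixture plus a
perseveration bonus π for repeating the previous choice:

$$P(a_1{=}a) \propto \exp\!\big(\beta_1[\,\omega\,Q_{MB}(a) + (1-\omega)\,Q_{MF}(a)\,] + \pi\,\mathrm{rep}(a)\big)$$

and the second stage is a plain softmax with temperature $\beta_2$. The free
parameters are $(\alpha_1,\alpha_2,\lambda,\beta_1,\beta_2,\pi,\omega)$;
ω = 1 is pure model-based control, ω = 0 pure model-free. Fitting is
hierarchical: a diagonal Gaussian prior over suitably transformed parameters
(logit for rates and ω, log for temperatures) is re-estimated from the
cohort by EM, and models are compared by iBIC.

## Worked example

```python
import numpy as np
from twostep import CohortSpec, generate_cohort, TwoStepModel, EMSettings
from twostep.inference import jonckheere_terpstra

spec = CohortSpec(group_sizes={"HC": 6, "SIB": 6, "OCD": 6})
data = generate_cohort(spec, np.random.default_rng(7))
trials = {s: g for s, g in data.trials.groupby("subject_id")}
res = TwoStepModel(trials).fit(EMSettings(seed=0, max_iter=10,
                                          n_starts_first=4, n_starts_later=1))
print(res.summary())
```

```
Two-step hybrid model — hierarchical EM fit
  subjects: 18   free parameters: 7
  EM iterations: 10 (converged: False)
  total log marginal: -3526.4 nats
  iBIC: 7177.1 (N = 7200 observations)

  population prior (transformed scale)
  param        mu     sigma   natural(mu)
  alpha1      -0.203    0.369       0.449
  alpha2      -0.111    0.227       0.472
  lam         -0.204    0.296       0.449
  beta1        1.621    0.365       5.059
  beta2        1.580    0.473       4.856
  pi_persev   -0.112    0.637      -0.112
  omega       -0.107    0.294       0.473
```

The prior table reports the population mean and s.d. per transformed
dimension and the natural-scale value at the mean: this toy cohort's average
learning rates sit near 0.45–0.47, softmax temperatures near 5, and the
average model-based weight near 0.47. Per-subject MAP estimates are in
`res.params`; `res.omega()` extracts the model-based weight for group
inference:

```python
truth = data.truth  # at full study size (n = 90) the ordering is detectable
by_group = {g: v["omega"].to_numpy() for g, v in
            generate_cohort(CohortSpec(), np.random.default_rng(7)).truth.groupby("group")}
jt = jonckheere_terpstra(by_group, ("OCD", "SIB", "HC"), n_perm=10_000,
                         rng=np.random.default_rng(1))
print(f"J = {jt.j_stat:.0f} (max {jt.j_max:.0f}), p = {jt.p_value:.4f}")
```

```
J = 1981 (max 2693), p = 0.0001
```

i.e. the generative model-based weights of the 90-subject default cohort
(group means 0.38 / 0.43 / 0.53 for OCD / SIB / HC at this seed) show a
significant ordered difference OCD < SIB < HC. At 18 subjects the same test
on *fitted* weights is underpowered — estimation noise at 200 trials is
substantial, which is exactly why the hierarchical prior and the full design
size matter.

A full pipeline run (fit → behavioral stats → inference → ROI correlations,
with a manifest of every default in force) is available as
`twostep report --config run.yaml` or `twostep.io.run_pipeline`; see
`twostep --help` for the `simulate`, `fit`, `analyze` and `recover`
subcommands.

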