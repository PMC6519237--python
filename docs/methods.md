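# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data generator behind `moralcog`, in enough detail to judge
what the test suite does and does not establish.

## Decision model

The harm-aversion utility model assigns the harmful option (more money
`Δm ≥ 0`, more shocks `Δs ≥ 0`, not both zero) the relative value
`V = (1 − κ)Δm − κΔs` and samples the choice from
`P(harm) = logistic(βV)`. Parameters:

| parameter | meaning | range | default in simulations |
|---|---|---|---|
| `κ_self` | harm aversion, shocks to self | [0, 1] | cohort draw, mean 0.45 |
| `κ_other` | harm aversion, shocks to other | [0, 1] | cohort draw, mean 0.55 |
| `β` | softmax consistency (1/noise) | ≥ 0 | cohort draw, median ≈ 5 |

Money is in arbitrary currency units and enters linearly; `κ/(1 − κ)`
is the money-per-shock exchange rate at indifference (`Δm/Δs` where
`V = 0`).

**Fitting.** Maximum likelihood via L-BFGS on unconstrained
coordinates: logit(κ) and log(β) (log-β capped at 20 to avoid overflow
on wild line-search steps). Five seeded starts guard against the flat
likelihood ridge at large β. Self and other trials share one β because
the choice rule has a single consistency parameter. Degenerate
responders (all choices identical within a target condition) are
unidentifiable; the fit returns a boundary estimate with a flag, and an
optional weak MAP prior (κ ~ Beta(1.1, 1.1), log β ~ N(1, 2²)) is
available for regularized pipelines. The reported log-likelihood is
always the pure data likelihood.

## Judgment model

Blame ratings live on a 0–100 scale (50 = neutral midpoint; the scale
is configurable). The model is linear in `Δm`, `Δs`, and their
interactions with the judge's own `κ_self`, `κ_other` (nine
coefficients b0–b8). Judge κs are supplied from the decision-model fit
and never re-estimated here. Fitting is ordinary least squares
(statsmodels), raw or with standardized predictors; identifying the
interaction terms requires both a decorrelated `Δm/Δs` design and κ
variation across judges, and rank-deficient designs raise an error
naming the collinear columns. Predictions are not clipped during
fitting (keeping OLS exact); simulated ratings are clipped to the
scale. Consequently OLS recovery is exact only when the generating
coefficients keep predictions inside the scale — the coverage
experiments use such coefficients, and real designs that censor at the
scale ends would need censored-regression machinery this package
deliberately omits.

## Inference model

The observer's belief over an agent's `κ_o` updates after each observed
choice. Learner-level parameters:

| parameter | meaning | default |
|---|---|---|
| `ω` | log belief volatility: the belief random walk gains variance `exp(ω)` per trial (κ² units) | −4 |
| `β_pred` | prediction consistency | 3 |
| `μ0`, `σ0` | prior mean and variance | 0.5, 1/12 |
| `β_agent` | agent consistency assumed in the likelihood | = `β_pred` |
| `α` | Rescorla–Wagner learning rate | 0.2 |

**Grid filter (oracle).** 201-point grid on [0, 1]. Per trial:
(1) diffuse the density with a Gaussian kernel of variance `exp(ω)`
under reflecting boundaries (diffusion is skipped when the kernel is
below 1e-6 grid cells, so `ω → −∞` reduces exactly to static Bayes);
(2) multiply by the Bernoulli likelihood of the observed choice under
the softmax utility model at each grid κ and renormalize. Zero
posterior mass raises with a diagnostic. Sequential updates with
diffusion disabled reproduce the batch posterior to ~1e-15, which the
suite asserts at 1e-10.

**Gaussian learner.** A two-moment (μ, σ) belief over κ in the
hierarchical-Gaussian-filter tradition: inflate variance by `exp(ω)`,
then project the exact one-observation posterior — reflected-Gaussian
prior times Bernoulli likelihood, restricted to [0, 1] — back onto the
Gaussian family by moment matching, computed with 81-node
Gauss–Legendre quadrature. The moment-matched mean obeys the
Gaussian-filter identity `μ_new = μ + σ̂ · ∂logZ/∂μ`: prediction errors
move the mean in proportion to the belief's uncertainty, the defining
contrast with a fixed-rate learner. Moment matching was chosen over a
single Laplace/Newton step because the softmax likelihood in κ is
nearly a step function at realistic `β(Δm + Δs)`, and a quadratic
expansion at the prior mean then badly overshoots and saturates;
matching the first two moments of the (effectively truncated) posterior
is the standard assumed-density remedy and tracks the grid oracle to a
mean |Δμ| ≈ 0.004–0.02 with trajectory correlation > 0.98 on 60-trial
sessions. The reflected prior mirrors the grid's reflecting boundaries;
without it the approximation leaks mass past the κ bounds and biases
beliefs about extreme agents.

**Rescorla–Wagner comparator.** A single running probability of the
harmful choice, `p̂ ← p̂ + α(y − p̂)`, initialized at 0.5. It ignores
trial features and carries no uncertainty, so it is the natural null
against the uncertainty-weighted learners (1 free parameter vs 2).

**Fitting and comparison.** The Bernoulli likelihood of the
participant's trial-by-trial predictions is maximized over (`ω`,
`β_pred`) — or `α` for RW — by Nelder–Mead with 3 seeded starts; `ω` is
unconstrained (log-variance scale), `β_pred` and `α` go through
log/logit transforms. `μ0`, `σ0` stay fixed by configuration. A
per-agent-ω flag fits one volatility per observed agent, enabling the
good/bad asymmetry analysis (the recovered ordering ω_bad > ω_good when
generated that way). `compare_models` reports AIC and BIC with ties
broken toward fewer parameters. In deterministic prediction mode, a
prediction probability of exactly 0.5 resolves to the less harmful
option (fixed, arbitrary tie-break).

**Probes.** Character ("nasty"–"nice") and uncertainty probes are
affine read-outs of (μ, σ) clipped to 0–100 — character slope 100
(so μ maps onto the scale directly), uncertainty slope 1200 (so the
uniform-belief variance 1/12 reads as 100). Probes are emitted every 8
trials by default and never feed back into the belief.

## Synthetic data

The generator produces the statistical structure the estimators assume,
not a facsimile of human behaviour:

- **Trials**: integer `Δm ∈ [1, 20]` currency units, `Δs ∈ [1, 10]`
  shocks; decorrelated designs resample until |r(Δm, Δs)| < 0.05
  (bounded retries).
- **Cohorts**: κ_self ~ truncated N(0.45, 0.15²), κ_other ~ truncated
  N(0.55, 0.15²) on [0.02, 0.98], log β ~ N(1.6, 0.3²). The cohort is
  hyperaltruistic by construction (mean κ_other > mean κ_self), matching
  the robust empirical pattern in this task family.
- **Agents**: the default good/bad pair has κ_o = 0.7 / 0.3, so their
  indifference exchange rates differ by 49/9 ≈ 5.44 — beyond the
  five-fold design separation the inference task requires. Agent
  β defaults to 5.
- **Sessions**: 60 trials per agent; participant predictions are
  sampled from the specified learner's prediction probabilities; the
  "ideal" learner is a near-zero-volatility grid filter. Judgment
  ratings add Gaussian noise (sd 5) and clip to scale.
- Every dataset ships with a ground-truth manifest; recovery tests read
  it only for scoring.

What passing recovery tests show: the estimators identify their own
generating processes at study-scale trial counts. What they do not
show: that human data satisfy the linearity, stationarity (constant κ
within a session), or noise assumptions — real ratings are discrete and
censored, real κ may drift, and real prediction noise need not be
softmax.

## Problem sizes

Simulation scales used by the test suite and the reproduction script
were chosen as typical for desk-scale recovery studies in this
literature: 50 subjects × 300 trials for decision recovery, 2 agents ×
60 trials per inference participant, 50 participants per model-recovery
arm, 200 replicates × 2,000 observations for judgment coverage.

## Known limitations

- The Gaussian learner is single-level: volatility `ω` is a fitted
  constant, not itself learned (no third level).
- The blame model has no praise/blame asymmetry and no censoring model.
- The influence metric's attraction weight λ is undefined for subjects
  whose baseline κ already matches the role model (excluded with a
  flag), and clamping λ to [0, 1] biases cohort means slightly upward
  when estimation noise is large relative to the κ gap.
- The hypocrisy index requires blame-like slopes (profit mitigates,
  pain aggravates); judges violating that pattern are flagged rather
  than scored.
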