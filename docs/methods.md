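# Methods

## The task

The Go/NoGo paradigm crosses outcome valence with the required
response, giving four conditions — Go-to-Win, Go-to-Avoid, NoGo-to-Win,
NoGo-to-Avoid — each signalled by its own stimulus and presented in a
randomly intermixed order (a full random permutation of the condition
multiset; no run-length constraints are imposed).  The optimal action
yields the positive outcome (reward delivered on Win trials, punishment
avoided on Avoid trials) with probability `p_optimal`, the suboptimal
action with `1 - p_optimal`.  Two built-in designs are provided: the
EEG-style design (40 trials per condition, 70/30 contingency) and the
fMRI-style design (60 trials per condition, 80/20).  Outcomes are coded
-1 (loss), 0 (neutral), +1 (win), so Win stimuli produce outcomes in
{0, +1} and Avoid stimuli in {-1, 0}.  Reaction times, lateralized
target discrimination and monetary bookkeeping are not modelled; only
the Go/NoGo choice matters to the models.

## The three models

All three models learn stimulus values from feedback and emit a
per-trial probability of responding Go.

**Heuristic RL.**  Instrumental values `V_I(s, a)` and Pavlovian values
`V_P(s)` follow Rescorla–Wagner updates with learning rate `α ∈ [0, 1]`
and outcome scaling `ρ > 0`:

    ΔV_I(s, a) = α (ρ r − V_I(s, a))        (taken action only)
    ΔV_P(s)    = α (ρ r − V_P(s))           (every trial)

The decision values are `V(s, Go) = V_I(s, Go) + π V_P(s) + b` and
`V(s, NoGo) = V_I(s, NoGo)`, where `π` is a fixed Pavlovian bias and
`b` a fixed Go bias.  Choice is a unit-temperature softmax mixed with a
lapse rate `ξ`:

    P(Go|s) = softmax(V) (1 − ξ) + ξ/2

`ρ` doubles as an effective inverse temperature, which is why the
softmax itself carries none.  Five free parameters: α, ρ, π, b, ξ.

**Fixed Bayesian.**  The learner entertains two predictive models of
the world: a stimulus-only (Pavlovian) predictor with Bernoulli
parameter per stimulus, and a stimulus–action (instrumental) predictor.
Posterior-mean estimates follow the same error-driven form but with a
*decaying* learning rate `1/η`, where `η` counts observations plus
prior pseudo-counts:

    η_s ← η_s + 1;     v_s ← v_s + (r − v_s)/η_s
    η_sa ← η_sa + 1;   v_sa ← v_sa + (r − v_sa)/η_sa   (taken action only)

This is exactly the posterior-mean recursion of a Beta–Bernoulli model
(counts increment before the update).  Values are signed (in [−1, 1]
for outcomes in {−1, 0, 1}): a negative value marks a
punishment-predictive stimulus.  The Pavlovian value of an action is
`v_s` for Go and 0 for NoGo (approach heuristic); the instrumental
value is `v_sa`.  Decision values are the convex combination

    V(s, a) = (1 − w) V_I(s, a) + w V_P(s, a)

with a *fixed* weight `w ∈ [0, 1]` on the Pavlovian predictor, passed
through a softmax with inverse temperature `β`.  No lapse or Go-bias
parameters.  Free parameters: β, the Pavlovian prior mean `v0_pav`
(shared across stimuli), the prior confidences `eta0_pav` and
`eta0_inst`, and `w_fixed` — five in total.  The instrumental prior
mean is pinned at 0 (no initial action preference), so only the
Pavlovian prior mean is free.

**Adaptive Bayesian.**  Identical to the Fixed model except that `w` is
the inferred posterior probability of the *uncontrollable* environment,
updated every trial.  With `w = 1/(1 + exp(−L))` and `L` the log-odds
favoring the uncontrollable world (initialized at 0, i.e. `w = 0.5`),
each outcome updates

    L ← L + e·log(m_s / m_sa) + (1 − e)·log((1 − m_s) / (1 − m_sa))

where `e = |r|` indicates that an outcome event (win or loss, as
opposed to a neutral outcome) occurred, and `m_s`, `m_sa` are the two
predictors' event probabilities.  This is the Bernoulli log-likelihood
ratio of the stimulus-only vs the stimulus–action predictor: when both
predict alike, `L` does not move; when actions carry no information,
the leaner stimulus-only predictor accrues evidence and `w` rises.
Four free parameters (no `w_fixed`).

### Numerical choices in the log-odds update

Three details are deliberate:

1. *Pre-update evaluation.* The predictors are scored on each outcome
   using the estimates held *before* learning from it, which is the
   prior-predictive comparison a sequential Bayes factor prescribes.
2. *Posterior-predictive magnitudes.*  The event probabilities fed to
   the update are `m = (η·|v| + 1)/(η + 2)` — the Beta
   posterior-predictive mean with uniform-prior (Laplace) smoothing —
   rather than the raw magnitude `|v|`.  The raw magnitude is
   degenerate whenever an estimate sits at or crosses zero (the
   instrumental prior mean is 0 by construction, and Pavlovian
   estimates cross zero whenever the prior has the wrong sign for a
   punishment stimulus): a clipped near-zero magnitude would inject
   single-trial evidence jumps of order `log(1/clip)` ≈ ±9, saturating
   `w` for entire sessions.  The smoothed form bounds single-trial
   evidence by about `log(η + 2)` and preserves the intended
   asymptotics (`m → |v|` as data accumulate).  In simulation it is the
   only variant we examined that jointly reproduces declining-weight
   dynamics in controllable sessions, rising weight under yoked
   (action-independent) outcomes, and the early-positive/late-negative
   Avoid go-bias pattern.
3. *Clipping.*  Magnitudes are clipped into `[1e-4, 1 − 1e-4]` before
   the logs as a final guard; with smoothing the clip is never active
   in practice.

Simulation and likelihood evaluation share one agent implementation,
so evaluating a generating model on its own simulated choices
reproduces the simulated latent trace exactly; the test suite asserts
this bit-for-bit.

## Fitting

Per-subject maximum likelihood.  Each parameter is transformed to the
real line by a scaled logit over its search box (α, ξ, w ∈ [0, 1];
ρ, β ∈ (0, 20]; η₀ ∈ [1, 100]; v0_pav ∈ [−1, 1]; π, b ∈ [−10, 10] —
generous ranges covering published fits), and L-BFGS-B runs from 10
random restarts drawn uniformly in the box (default; configurable).
Per-trial choice probabilities are floored at 1e-12 inside the log.
Convergence means optimizer-reported success plus no objective
degradation beyond 1e-6.  Model evidence is approximated by
`−BIC/2 = −(k ln n)/2 − nll`, with k = 5 (RL), 5 (Fixed), 4 (Adaptive;
the initial log-odds is pinned at 0) and n the subject's trial count.

## Group-level comparison

Random-effects Bayesian model selection: subjects' generating models
are draws from unknown population frequencies with a uniform Dirichlet
prior (α₀ = 1).  The variational updates iterate to |Δα| < 1e-6 (cap
500).  Exceedance probabilities are Monte-Carlo estimates from 10⁶
Dirichlet draws (the K = 2 Beta-tail closed form serves as a test
oracle only).  The Bayes omnibus risk compares the RFX model's
variational free energy against the exact evidence of the null
(equal-frequency) model, in which each subject's data are a 1/K
mixture over models; protected exceedance probabilities are
`PXP = (1 − BOR)·XP + BOR/K`.  Both quantities are invariant to adding
a constant to any subject's row of log evidences.

## Behavioral analyses

*Go bias* is accuracy on Go-required minus accuracy on NoGo-required
trials.  The weight-quantile analysis bins each subject's trials by
within-subject rank quantiles of the pre-choice `w` (default 5 bins;
ties broken by trial order, so bin sizes differ by at most one trial;
subjects with constant `w` are excluded with a warning), computes the
go bias per bin and valence, and compares top vs bottom bin with a
paired t-test.  The early/late analysis takes the first and last 40
trials of the intermixed sequence (positional windows; the go bias is
computed on Avoid-condition trials by default, configurable to Win or
all).  Confound checks correlate `w` with the instrumental and
Pavlovian value traces per subject, summarize with the group median and
a Wilcoxon signed-rank test, and quantify evidence for the null with a
one-sample JZS Bayes factor on the Fisher-z-transformed correlations
(Cauchy prior scale √2/2, the conventional default; computed by 1-D
adaptive quadrature of the marginal likelihood and cross-checked
against pingouin in the tests).  Expected accuracy — the model's
probability of the optimal action, `p_go` on Go-required trials and
`1 − p_go` otherwise — serves as a confidence proxy.

## Synthetic cohorts and what they can show

The generator produces agents of any of the three models on either
design.  One master seed drives everything; per-subject streams are
spawned deterministically, so cohorts are bit-reproducible.  For
recovery experiments the true Adaptive-model parameters are drawn per
subject as β ~ U[1, 10], v0_pav ~ U[−0.25, 0.75] (mass above zero,
matching the empirical preponderance of positive initial Pavlovian
values), eta0_pav, eta0_inst ~ U[1, 10].  The qualitative go-bias
demonstrations restrict v0_pav to U[0.25, 0.75], the regime in which
the early Avoid go bias is predicted to be positive.

Synthetic agents are ideal observers of the generative model: they lack
attentional lapses, session drift, and individual differences beyond
the sampled parameters.  Passing recovery and pattern tests therefore
shows that the estimation and comparison machinery is sound and that
the model family produces the claimed behavioral signatures — not that
human data would be fit equally well.  Because fitted ideal agents
suppress Pavlovian influence more efficiently than humans, late-session
effects are smaller than in real data; the pattern tests are sign
tests over replicate cohorts rather than effect-size comparisons.

## Problem sizes

The full parameter-recovery experiment uses the fMRI design with 30
subjects and 10-restart fits (~1–2 minutes); model recovery uses 15
subjects with all three models fitted (~2 minutes); the behavioral
pattern experiment uses 20 cohorts of 15 simulated subjects
(simulation only, no fitting).  All are exercised end-to-end by the
test suite and the acceptance script.

## Known limitations

- The exact free-parameter inventory of the Bayesian models (which
  priors are shared across stimuli and valences) is a design decision:
  one shared Pavlovian prior mean and two shared confidences; the
  instrumental prior mean is fixed at 0.
- BIC is a large-sample approximation to the marginal likelihood; with
  160–240 trials per subject it penalizes the 5-parameter models by
  only ~2.5 log-units relative to the Adaptive model's 4.
- The prior-confidence parameter of the Pavlovian values is weakly
  identified by design (its influence fades once counts accumulate),
  and it recovers worst in the recovery experiment — a property of the
  model, not a defect of the optimizer.
- `eta0` upper fit bound (100) exceeds the sampler range ([1, 10]), so
  recovered confidences can escape upward for near-flat likelihoods;
  this depresses the confidence-parameter recovery correlations and is
  left as-is deliberately.
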