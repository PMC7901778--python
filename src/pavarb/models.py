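"""Trial-level likelihood engines for the three competing learning models.

Three models of Go/NoGo choice compete to explain behavior:

``rl``
    A heuristic reinforcement-learning model.  Instrumental values
    ``V_I(s, a)`` and Pavlovian values ``V_P(s)`` follow Rescorla-Wagner
    updates with a constant learning rate ``alpha`` and outcome scaling
    ``rho``.  The decision value for Go adds a fixed Pavlovian bias
    ``pi * V_P(s)`` and a fixed Go bias ``b``; choice is a
    unit-temperature softmax mixed with a lapse probability ``xi``.

``fixed``
    A Bayesian learner that maintains Beta posterior-mean estimates of
    the outcome probability under two predictive models of the world: a
    stimulus-only (Pavlovian) predictor and a stimulus-action
    (instrumental) predictor.  Learning rates decay as ``1 / eta`` with
    the number of observations.  Decision values are a convex
    combination ``V = (1 - w) V_I + w V_P`` with a *fixed* weight ``w``
    on the Pavlovian predictor, passed through a softmax with inverse
    temperature ``beta``.

``adaptive``
    Same as ``fixed``, except the Pavlovian weight is the posterior
    probability of the uncontrollable environment, updated every trial
    from the log-likelihood ratio of the two predictors.  ``w`` is the
    logistic transform of the accumulated log-odds ``L`` (``L = 0``
    before any data, giving ``w = 0.5``).

Simulation (:mod:`pavarb.simulate`) and likelihood evaluation
(:func:`run_model`) share the agent classes defined here, so evaluating
a generating model on its own simulated choices reproduces the
simulation trace exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .task import GO, NOGO

#: magnitudes are clipped into [CLIP, 1 - CLIP] before entering the
#: log-odds update, so extreme priors cannot produce infinite evidence
CLIP = 1e-4

MODEL_LABELS = ("rl", "fixed", "adaptive")


class InvalidParametersError(ValueError):
    """Raised when parameters do not match the requested model."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class RLParams:
    """Free parameters of the heuristic RL model.

    alpha : learning rate in [0, 1]
    rho   : outcome scaling factor (> 0)
    pi    : Pavlovian bias weight on V_P for the Go action
    b     : fixed Go bias
    xi    : lapse probability in [0, 1]
    """

    alpha: float
    rho: float
    pi: float
    b: float
    xi: float

    def validate(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParametersError(f"alpha must be in [0,1], got {self.alpha}")
        if self.rho <= 0:
            raise InvalidParametersError(f"rho must be > 0, got {self.rho}")
        if not 0.0 <= self.xi <= 1.0:
            raise InvalidParametersError(f"xi must be in [0,1], got {self.xi}")
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise InvalidParametersError(f"{f.name} is not finite")


@dataclass
class FixedBayesParams:
    """Free parameters of the Fixed Bayesian model.

    beta      : softmax inverse temperature (>= 0)
    v0_pav    : prior mean of the Pavlovian values, in [-1, 1]
    eta0_pav  : prior confidence (pseudo-count) of the Pavlovian values (> 0)
    eta0_inst : prior confidence of the instrumental values (> 0)
    w_fixed   : constant Pavlovian weight in [0, 1]
    """

    beta: float
    v0_pav: float
    eta0_pav: float
    eta0_inst: float
    w_fixed: float

    def validate(self):
        _validate_bayes_common(self)
        if not 0.0 <= self.w_fixed <= 1.0:
            raise InvalidParametersError(f"w_fixed must be in [0,1], got {self.w_fixed}")


@dataclass
class AdaptiveBayesParams:
    """Free parameters of the Adaptive Bayesian model.

    Same as :class:`FixedBayesParams` but without ``w_fixed``: the
    weight is inferred on-line, starting from log-odds ``L = 0``.
    """

    beta: float
    v0_pav: float
    eta0_pav: float
    eta0_inst: float

    def validate(self):
        _validate_bayes_common(self)


def _validate_bayes_common(p):
    if p.beta < 0:
        raise InvalidParametersError(f"beta must be >= 0, got {p.beta}")
    if not -1.0 <= p.v0_pav <= 1.0:
        raise InvalidParametersError(f"v0_pav must be in [-1,1], got {p.v0_pav}")
    if p.eta0_pav <= 0 or p.eta0_inst <= 0:
        raise InvalidParametersError("prior confidences must be > 0")
    for f in fields(p):
        if not math.isfinite(getattr(p, f.name)):
            raise InvalidParametersError(f"{f.name} is not finite")


PARAM_CLASSES = {"rl": RLParams, "fixed": FixedBayesParams, "adaptive": AdaptiveBayesParams}

#: free-parameter count per model (for the BIC)
N_PARAMS = {"rl": 5, "fixed": 5, "adaptive": 4}


def make_params(model_label: str, **kwargs):
    """Build and validate a parameter object for *model_label*."""
    try:
        cls = PARAM_CLASSES[model_label]
    except KeyError:
        raise InvalidParametersError(f"unknown model {model_label!r}") from None
    try:
        p = cls(**kwargs)
    except TypeError as exc:
        raise InvalidParametersError(str(exc)) from None
    p.validate()
    return p


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def rl_integrate(v_inst_go: float, v_inst_nogo: float, v_pav: float,
                 params: RLParams) -> tuple[float, float]:
    """Integrated decision values of the RL model.

    ``V(s, Go) = V_I(s, Go) + pi * V_P(s) + b`` and
    ``V(s, NoGo) = V_I(s, NoGo)``.
    """
    return v_inst_go + params.pi * v_pav + params.b, v_inst_nogo


def rl_action_prob(v_go: float, v_nogo: float, xi: float) -> float:
    """Softmax choice probability with lapse mixing.

    ``P(Go) = softmax(V_go, V_nogo) * (1 - xi) + xi / 2`` at unit inverse
    temperature (the outcome scaling ``rho`` plays the temperature role).
    """
    if not 0.0 <= xi <= 1.0:
        raise InvalidParametersError(f"xi must be in [0,1], got {xi}")
    return _softmax_go(v_go, v_nogo, 1.0) * (1.0 - xi) + xi / 2.0


def rl_update(state: "ValueState", stimulus: int, action: int, outcome: float,
              params: RLParams) -> "ValueState":
    """Rescorla-Wagner update (in place; the state is also returned).

    Only the taken action's instrumental value moves; the Pavlovian
    value of the stimulus moves on every trial.
    """
    target = params.rho * outcome
    vi = state.v_inst[stimulus][action]
    state.v_inst[stimulus][action] = vi + params.alpha * (target - vi)
    vp = state.v_pav[stimulus]
    state.v_pav[stimulus] = vp + params.alpha * (target - vp)
    return state


def bayes_value_update(state: "ValueState", stimulus: int, action: int,
                       outcome: float) -> "ValueState":
    """Beta posterior-mean recursion with decaying learning rate.

    Counts increment first; the update then uses ``1 / eta`` with the
    post-increment count, which is exactly the posterior-mean recursion
    of a Beta-Bernoulli model (prior pseudo-count ``eta0``, prior mean
    the initial value).  The stimulus count and Pavlovian value move on
    every trial; the instrumental pair only for the taken action.
    """
    state.eta_pav[stimulus] += 1.0
    vp = state.v_pav[stimulus]
    state.v_pav[stimulus] = vp + (outcome - vp) / state.eta_pav[stimulus]
    state.eta_inst[stimulus][action] += 1.0
    vi = state.v_inst[stimulus][action]
    state.v_inst[stimulus][action] = vi + (outcome - vi) / state.eta_inst[stimulus][action]
    return state


def bayes_pav_value(v_pav: float, action: int) -> float:
    """Pavlovian value of an action: ``v_pav`` for Go, 0 for NoGo."""
    return v_pav if action == GO else 0.0


def bayes_integrate(v_inst: float, v_pav_action: float, w: float) -> float:
    """Convex combination ``V = (1 - w) V_I + w V_P``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"Pavlovian weight must be in [0,1], got {w}")
    return (1.0 - w) * v_inst + w * v_pav_action


def bayes_action_prob(v_go: float, v_nogo: float, beta: float) -> float:
    """Softmax ``P(Go) = exp(beta V_go) / (exp(beta V_go) + exp(beta V_nogo))``."""
    return _softmax_go(v_go, v_nogo, beta)


def _softmax_go(v_go: float, v_nogo: float, beta: float) -> float:
    # stable two-option softmax: logistic of the scaled value difference
    x = beta * (v_go - v_nogo)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def logodds_update(L: float, theta_s_hat: float, theta_sa_hat: float,
                   outcome: float) -> float:
    """One-step update of the log-odds favoring the uncontrollable world.

    The two predictors are scored on whether an outcome *event* occurred
    (``e = |r|``, 1 for a win or a loss, 0 for a neutral outcome) using
    their event-probability estimates, the magnitudes ``|theta_s|``
    (stimulus-only) and ``|theta_sa|`` (stimulus-action):

    ``L' = L + e log(m_s / m_sa) + (1 - e) log((1 - m_s) / (1 - m_sa))``

    This is the Bernoulli log-likelihood ratio of the Pavlovian vs the
    instrumental predictor, so identical predictions leave ``L``
    unchanged.  Magnitudes are clipped into ``[CLIP, 1 - CLIP]``.
    """
    m_s = min(max(abs(theta_s_hat), CLIP), 1.0 - CLIP)
    m_sa = min(max(abs(theta_sa_hat), CLIP), 1.0 - CLIP)
    e = abs(outcome)
    return L + e * math.log(m_s / m_sa) + (1.0 - e) * math.log((1.0 - m_s) / (1.0 - m_sa))


def predictive_event_prob(value: float, eta: float) -> float:
    """Posterior-predictive probability of an outcome event.

    A predictor with effective count ``eta`` and value estimate ``value``
    assigns the next outcome event (win or loss, as opposed to a neutral
    outcome) probability ``(eta * |value| + 1) / (eta + 2)`` — the
    Beta posterior-predictive mean with uniform-prior (Laplace)
    smoothing.  Feeding these smoothed magnitudes to
    :func:`logodds_update` keeps single-trial evidence bounded by about
    ``log(eta + 2)`` even when a value estimate sits at, or crosses,
    zero, where the raw magnitude would be degenerate.
    """
    if eta < 0:
        raise ValueError(f"eta must be >= 0, got {eta}")
    return (eta * abs(value) + 1.0) / (eta + 2.0)


def weight_from_logodds(L: float) -> float:
    """Pavlovian weight ``w = 1 / (1 + exp(-L))``."""
    if not math.isfinite(L):
        raise ValueError(f"log-odds must be finite, got {L}")
    if L >= 0:
        return 1.0 / (1.0 + math.exp(-L))
    e = math.exp(L)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# agent state and steppers (shared by simulation and likelihood evaluation)
# ---------------------------------------------------------------------------

@dataclass
class ValueState:
    """Mutable per-subject learning state.

    v_inst / eta_inst are indexed ``[stimulus][action]`` with action
    0 = NoGo, 1 = Go; v_pav / eta_pav are indexed ``[stimulus]``.  ``L``
    is the log-odds favoring the uncontrollable environment (used by the
    Adaptive model only).
    """

    v_inst: list
    v_pav: list
    eta_inst: list
    eta_pav: list
    L: float = 0.0


class _Agent:
    """One model's per-trial policy/update engine."""

    def p_go(self, stimulus: int) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def update(self, stimulus: int, action: int, outcome: float) -> None:  # pragma: no cover
        raise NotImplementedError

    @property
    def w(self):
        """Pavlovian weight currently in force (None for the RL model)."""
        return None


class RLAgent(_Agent):
    def __init__(self, params: RLParams, n_stimuli: int = 4):
        params.validate()
        self.params = params
        self.state = ValueState(
            v_inst=[[0.0, 0.0] for _ in range(n_stimuli)],
            v_pav=[0.0] * n_stimuli,
            eta_inst=[[0.0, 0.0] for _ in range(n_stimuli)],
            eta_pav=[0.0] * n_stimuli,
        )

    def values(self, stimulus: int) -> tuple[float, float]:
        s = self.state
        return rl_integrate(s.v_inst[stimulus][GO], s.v_inst[stimulus][NOGO],
                            s.v_pav[stimulus], self.params)

    def prob_from_values(self, v_go: float, v_nogo: float) -> float:
        return rl_action_prob(v_go, v_nogo, self.params.xi)

    def p_go(self, stimulus: int) -> float:
        return self.prob_from_values(*self.values(stimulus))

    def update(self, stimulus: int, action: int, outcome: float) -> None:
        rl_update(self.state, stimulus, action, outcome, self.params)


class BayesAgent(_Agent):
    """Fixed or Adaptive Bayesian learner (``adaptive=True`` switches on
    the per-trial log-odds update of the Pavlovian weight)."""

    def __init__(self, params, adaptive: bool, n_stimuli: int = 4):
        params.validate()
        if adaptive and isinstance(params, FixedBayesParams):
            raise InvalidParametersError("adaptive model takes AdaptiveBayesParams")
        if not adaptive and not isinstance(params, FixedBayesParams):
            raise InvalidParametersError("fixed model takes FixedBayesParams")
        self.params = params
        self.adaptive = adaptive
        self.state = ValueState(
            v_inst=[[0.0, 0.0] for _ in range(n_stimuli)],
            v_pav=[params.v0_pav] * n_stimuli,
            eta_inst=[[params.eta0_inst, params.eta0_inst] for _ in range(n_stimuli)],
            eta_pav=[params.eta0_pav] * n_stimuli,
            L=0.0,
        )

    @property
    def w(self) -> float:
        if self.adaptive:
            return weight_from_logodds(self.state.L)
        return self.params.w_fixed

    def values(self, stimulus: int) -> tuple[float, float]:
        s, w = self.state, self.w
        v_go = bayes_integrate(s.v_inst[stimulus][GO],
                               bayes_pav_value(s.v_pav[stimulus], GO), w)
        v_nogo = bayes_integrate(s.v_inst[stimulus][NOGO],
                                 bayes_pav_value(s.v_pav[stimulus], NOGO), w)
        return v_go, v_nogo

    def prob_from_values(self, v_go: float, v_nogo: float) -> float:
        return bayes_action_prob(v_go, v_nogo, self.params.beta)

    def p_go(self, stimulus: int) -> float:
        return self.prob_from_values(*self.values(stimulus))

    def update(self, stimulus: int, action: int, outcome: float) -> None:
        s = self.state
        if self.adaptive:
            # evidence is computed at pre-update estimates (the predictors
            # are scored on the observation before learning from it), using
            # posterior-predictive event probabilities so that evidence per
            # trial stays bounded
            m_s = predictive_event_prob(s.v_pav[stimulus], s.eta_pav[stimulus])
            m_sa = predictive_event_prob(s.v_inst[stimulus][action],
                                         s.eta_inst[stimulus][action])
            s.L = logodds_update(s.L, m_s, m_sa, outcome)
        bayes_value_update(s, stimulus, action, outcome)


def make_agent(model_label: str, params, n_stimuli: int = 4) -> _Agent:
    """Instantiate the stepper for *model_label* with *params*."""
    if model_label == "rl":
        if not isinstance(params, RLParams):
            raise InvalidParametersError("rl model takes RLParams")
        return RLAgent(params, n_stimuli)
    if model_label == "fixed":
        return BayesAgent(params, adaptive=False, n_stimuli=n_stimuli)
    if model_label == "adaptive":
        return BayesAgent(params, adaptive=True, n_stimuli=n_stimuli)
    raise InvalidParametersError(f"unknown model {model_label!r}")


# ---------------------------------------------------------------------------
# trace container and likelihood evaluation
# ---------------------------------------------------------------------------

@dataclass
class LatentTrace:
    """Per-trial model internals, aligned to trial order.

    All quantities are *pre-choice*: the values, weight and P(Go) in
    force when the action on that trial was selected.  ``w`` is NaN for
    the RL model (no weight in [0, 1] is defined for it).
    """

    v_inst_go: np.ndarray
    v_inst_nogo: np.ndarray
    v_pav: np.ndarray
    w: np.ndarray
    p_go: np.ndarray
    v_go: np.ndarray
    v_nogo: np.ndarray

    def __len__(self):
        return len(self.p_go)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "trial_index": np.arange(len(self)),
            "v_inst_go": self.v_inst_go, "v_inst_nogo": self.v_inst_nogo,
            "v_pav": self.v_pav, "w": self.w, "p_go": self.p_go,
            "v_go": self.v_go, "v_nogo": self.v_nogo,
        })


def run_model(stimuli, actions, outcomes, model_label: str, params,
              n_stimuli: int = 4, record_trace: bool = True):
    """Evaluate one subject's trial sequence under a model.

    Parameters
    ----------
    stimuli, actions, outcomes : sequences of int
        Per-trial stimulus index (0..3), action (1 = Go, 0 = NoGo) and
        outcome (-1, 0, +1), ordered by trial.
    record_trace : bool
        Skip latent-trace recording (slightly faster; used inside the
        optimizer loop).

    Returns
    -------
    p_go : ndarray
        Pre-choice P(Go) per trial.
    loglik : ndarray
        Log-likelihood of the observed action per trial.
    trace : LatentTrace or None
    """
    agent = make_agent(model_label, params, n_stimuli)
    T = len(stimuli)
    p_go = np.empty(T)
    loglik = np.empty(T)
    if record_trace:
        tr = {k: np.empty(T) for k in ("v_inst_go", "v_inst_nogo", "v_pav",
                                       "w", "v_go", "v_nogo")}
    floor = 1e-300
    log = math.log
    for t in range(T):
        s = int(stimuli[t])
        if not 0 <= s < n_stimuli:
            raise ValueError(f"unknown stimulus id {s} at trial {t}")
        a = int(actions[t])
        r = float(outcomes[t])
        v_go, v_nogo = agent.values(s)
        p = agent.prob_from_values(v_go, v_nogo)
        if record_trace:
            st = agent.state
            w = agent.w
            tr["v_inst_go"][t] = st.v_inst[s][GO]
            tr["v_inst_nogo"][t] = st.v_inst[s][NOGO]
            tr["v_pav"][t] = st.v_pav[s]
            tr["w"][t] = math.nan if w is None else w
            tr["v_go"][t] = v_go
            tr["v_nogo"][t] = v_nogo
        p_go[t] = p
        pa = p if a == GO else 1.0 - p
        loglik[t] = log(pa if pa > floor else floor)
        agent.update(s, a, r)
    trace = None
    if record_trace:
        trace = LatentTrace(tr["v_inst_go"], tr["v_inst_nogo"], tr["v_pav"],
                            tr["w"], p_go.copy(), tr["v_go"], tr["v_nogo"])
    return p_go, loglik, trace
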