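"""Per-subject maximum-likelihood estimation and BIC model evidence.

Each model is fitted to each subject independently by minimizing the
negative log-likelihood of the observed Go/NoGo choices.  Optimization
runs in an unconstrained space obtained by a scaled-logit transform of
every parameter's box, with multiple random restarts drawn uniformly
within the bounds.  Model evidence is approximated as ``-BIC / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import models
from .data import BehavioralDataset

#: search box per parameter, per model (order defines the fit vector)
PARAM_BOUNDS = {
    "rl": {
        "alpha": (0.0, 1.0),
        "rho": (1e-3, 20.0),
        "pi": (-10.0, 10.0),
        "b": (-10.0, 10.0),
        "xi": (0.0, 1.0),
    },
    "fixed": {
        "beta": (1e-3, 20.0),
        "v0_pav": (-1.0, 1.0),
        "eta0_pav": (1.0, 100.0),
        "eta0_inst": (1.0, 100.0),
        "w_fixed": (0.0, 1.0),
    },
    "adaptive": {
        "beta": (1e-3, 20.0),
        "v0_pav": (-1.0, 1.0),
        "eta0_pav": (1.0, 100.0),
        "eta0_inst": (1.0, 100.0),
    },
}

#: per-trial choice probabilities are floored at this value inside the log
LIK_FLOOR = 1e-12

_ZMAX = 30.0


def _to_native(z, bounds):
    """Scaled-logit transform from unconstrained z to the parameter box."""
    out = {}
    for zi, (name, (lo, hi)) in zip(z, bounds.items()):
        zi = min(max(zi, -_ZMAX), _ZMAX)
        s = 1.0 / (1.0 + math.exp(-zi)) if zi >= 0 else (
            math.exp(zi) / (1.0 + math.exp(zi)))
        out[name] = lo + (hi - lo) * s
    return out


def _to_z(values, bounds):
    z = []
    for name, (lo, hi) in bounds.items():
        s = (values[name] - lo) / (hi - lo)
        s = min(max(s, 1e-10), 1.0 - 1e-10)
        z.append(math.log(s / (1.0 - s)))
    return np.array(z)


def negative_log_likelihood(subject_trials, model_label: str, params) -> float:
    """``-sum_t log P(action_t)`` for one subject under one model.

    *subject_trials* may be a subject's trial DataFrame or a
    ``(stimuli, actions, outcomes)`` triple of arrays.
    """
    stim, act, out = _as_arrays(subject_trials)
    p_go, _, _ = models.run_model(stim, act, out, model_label, params,
                                  record_trace=False)
    p_act = np.where(act == 1, p_go, 1.0 - p_go)
    return float(-np.sum(np.log(np.maximum(p_act, LIK_FLOOR))))


def _as_arrays(subject_trials):
    if isinstance(subject_trials, tuple):
        return subject_trials
    df = subject_trials
    return (df["stimulus_id"].to_numpy(int), df["action"].to_numpy(int),
            df["outcome"].to_numpy(int))


def bic(nll: float, k: int, n: int) -> float:
    """Bayesian information criterion ``k ln(n) + 2 nll`` (lower = better).

    ``-bic / 2`` is the log-evidence approximation used for group-level
    model comparison.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) + 2.0 * nll


@dataclass
class FitResult:
    """One subject x model maximum-likelihood fit."""

    subject_id: object
    model_label: str
    params: object
    nll: float
    bic: float
    n_trials: int
    n_restarts_used: int
    converged: bool

    @property
    def log_evidence(self) -> float:
        return -self.bic / 2.0

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "model": self.model_label,
               "nll": self.nll, "bic": self.bic, "n_trials": self.n_trials,
               "converged": self.converged}
        row.update(vars(self.params))
        return row


def fit_subject(subject_trials, model_label: str, n_restarts: int = 10,
                seed: int = 0, subject_id=None) -> FitResult:
    """Fit one model to one subject's choices by multi-start MLE.

    Starting points are drawn uniformly within the parameter bounds from
    a generator seeded with *seed*, so the fit is reproducible.  The best
    local optimum over restarts is returned; ``converged`` records
    whether any restart both satisfied the optimizer's own success
    criterion and improved on its starting objective by more than the
    tolerance.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    bounds = PARAM_BOUNDS[model_label]
    stim, act, out = _as_arrays(subject_trials)
    n_trials = len(stim)
    if subject_id is None and not isinstance(subject_trials, tuple):
        ids = subject_trials["subject_id"].unique()
        subject_id = ids[0] if len(ids) == 1 else None
    rng = np.random.default_rng(seed)

    def objective(z):
        params = models.make_params(model_label, **_to_native(z, bounds))
        return negative_log_likelihood((stim, act, out), model_label, params)

    best = None
    converged = False
    for _ in range(n_restarts):
        start = {name: rng.uniform(lo, hi) for name, (lo, hi) in bounds.items()}
        z0 = _to_z(start, bounds)
        res = minimize(objective, z0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        if res.success and (objective(z0) - res.fun) > -1e-6:
            converged = True
    params = models.make_params(model_label, **_to_native(best.x, bounds))
    nll = float(best.fun)
    k = models.N_PARAMS[model_label]
    return FitResult(subject_id, model_label, params, nll,
                     bic(nll, k, n_trials), n_trials, n_restarts, converged)


@dataclass
class CohortFit:
    """All subject x model fits for one dataset."""

    results: list
    model_labels: tuple
    subject_ids: list

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def result(self, subject_id, model_label) -> FitResult:
        for r in self.results:
            if r.subject_id == subject_id and r.model_label == model_label:
                return r
        raise KeyError((subject_id, model_label))

    def log_evidence_matrix(self) -> np.ndarray:
        """Subjects x models matrix of ``-BIC/2`` log evidences."""
        m = np.empty((len(self.subject_ids), len(self.model_labels)))
        for i, sid in enumerate(self.subject_ids):
            for j, lab in enumerate(self.model_labels):
                m[i, j] = self.result(sid, lab).log_evidence
        return m


def fit_cohort(dataset: BehavioralDataset, model_labels=("rl", "fixed", "adaptive"),
               n_restarts: int = 10, seed: int = 0) -> CohortFit:
    """Fit every model to every subject independently.

    Per-(subject, model) restart streams are derived deterministically
    from *seed*, so a cohort fit is bit-reproducible.  A failed subject
    fit is recorded with ``converged=False`` rather than aborting the
    cohort.
    """
    if dataset.n_subjects < 1:
        raise ValueError("dataset has no subjects")
    model_labels = tuple(model_labels)
    results = []
    sids = dataset.subject_ids
    for i, sid in enumerate(sids):
        arrays = dataset.arrays(sid)
        for j, lab in enumerate(model_labels):
            sub_seed = _derive_fit_seed(seed, i, j)
            results.append(fit_subject(arrays, lab, n_restarts=n_restarts,
                                       seed=sub_seed, subject_id=sid))
    return CohortFit(results, model_labels, sids)


def _derive_fit_seed(master_seed: int, subject_index: int, model_index: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(subject_index, model_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
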