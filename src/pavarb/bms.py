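"""Random-effects Bayesian model selection (RFX-BMS).

Given a subjects x models matrix of log model evidences (here the BIC
approximation ``-BIC/2``), the group is modelled as a population in
which each subject's generating model is drawn from unknown frequencies
``r ~ Dirichlet(alpha)``.  A variational scheme estimates the posterior
concentration ``alpha``; exceedance probabilities (XP) give the
posterior probability that each model is the most frequent one; the
Bayes omnibus risk (BOR) is the posterior probability of the null model
in which all frequencies are equal, and protected exceedance
probabilities (PXP) blend the two:

    PXP_k = (1 - BOR) * XP_k + BOR / K
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


class InvalidEvidenceError(ValueError):
    """Raised when the log-evidence matrix is unusable."""


@dataclass
class BMSResult:
    """Group-level model-comparison summary.

    alpha : Dirichlet concentration over the K models
    expected_frequencies : posterior mean model frequencies (sum to 1)
    xp : exceedance probabilities (sum to 1)
    bor : Bayes omnibus risk in [0, 1]
    pxp : protected exceedance probabilities (sum to 1)
    """

    alpha: np.ndarray
    expected_frequencies: np.ndarray
    xp: np.ndarray
    bor: float
    pxp: np.ndarray
    model_labels: tuple = None

    def to_dict(self) -> dict:
        d = {"alpha": self.alpha.tolist(),
             "expected_frequencies": self.expected_frequencies.tolist(),
             "xp": self.xp.tolist(), "bor": float(self.bor),
             "pxp": self.pxp.tolist()}
        if self.model_labels is not None:
            d["model_labels"] = list(self.model_labels)
        return d


def _check_matrix(log_evidence) -> np.ndarray:
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise InvalidEvidenceError("need a subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(lme)):
        raise InvalidEvidenceError("log evidences must be finite")
    return lme


def rfx_bms(log_evidence, alpha0: float = 1.0, tol: float = 1e-6,
            max_iter: int = 500):
    """Variational Dirichlet-multinomial updates for RFX-BMS.

    Returns ``(alpha, expected_frequencies, responsibilities)``; the
    responsibilities are the posterior per-subject model assignment
    probabilities.  The result is invariant to adding a constant to any
    subject's row of *log_evidence*.
    """
    lme = _check_matrix(log_evidence)
    n, k = lme.shape
    lme = lme - lme.max(axis=1, keepdims=True)
    a0 = np.full(k, float(alpha0))
    alpha = a0.copy()
    for _ in range(max_iter):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        resp = u / u.sum(axis=1, keepdims=True)
        new_alpha = a0 + resp.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    logu = lme + digamma(alpha) - digamma(alpha.sum())
    logu -= logu.max(axis=1, keepdims=True)
    u = np.exp(logu)
    resp = u / u.sum(axis=1, keepdims=True)
    return alpha, alpha / alpha.sum(), resp


def exceedance_probability(alpha, n_samples: int = 1_000_000,
                           seed: int = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities from Dirichlet(alpha).

    ``xp_k = P(r_k > r_j for all j != k)``, estimated from *n_samples*
    Dirichlet draws.  (For K = 2 the closed form is the Beta tail
    ``P(r_1 > 0.5)``, which this estimate matches to Monte-Carlo error.)
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    k = len(alpha)
    counts = np.zeros(k)
    # draw in blocks to bound memory
    block = 200_000
    remaining = int(n_samples)
    while remaining > 0:
        b = min(block, remaining)
        draws = rng.dirichlet(alpha, size=b)
        winners = np.argmax(draws, axis=1)
        counts += np.bincount(winners, minlength=k)
        remaining -= b
    return counts / n_samples


def _rfx_free_energy(lme, alpha, resp, alpha0: float = 1.0) -> float:
    """Variational free energy of the RFX model (lower bound on its
    log evidence)."""
    n, k = lme.shape
    a0 = np.full(k, float(alpha0))
    dg = digamma(alpha) - digamma(alpha.sum())
    e_log_p_r = gammaln(a0.sum()) - gammaln(a0).sum() + ((a0 - 1.0) * dg).sum()
    h_r = -(gammaln(alpha.sum()) - gammaln(alpha).sum()
            + ((alpha - 1.0) * dg).sum())
    e_log_lik = float(np.sum(resp * (lme + dg)))
    with np.errstate(divide="ignore", invalid="ignore"):
        h_m = -float(np.nansum(resp * np.where(resp > 0, np.log(resp), 0.0)))
    return e_log_p_r + h_r + e_log_lik + h_m


def null_log_evidence(log_evidence) -> float:
    """Exact log evidence of the null (equal-frequency) model:
    each subject's data are a 1/K mixture over models."""
    lme = _check_matrix(log_evidence)
    n, k = lme.shape
    return float(np.sum(logsumexp(lme, axis=1) - np.log(k)))


def bayes_omnibus_risk(log_evidence, alpha=None, resp=None,
                       alpha0: float = 1.0) -> float:
    """Posterior probability that model frequencies are uniform (null).

    Compares the free energy of the RFX model against the exact
    evidence of the null model under equal prior odds.  Invariant to
    per-subject row shifts of the evidence matrix.
    """
    lme = _check_matrix(log_evidence)
    lme = lme - lme.max(axis=1, keepdims=True)
    if alpha is None or resp is None:
        alpha, _, resp = rfx_bms(lme, alpha0=alpha0)
    f1 = _rfx_free_energy(lme, alpha, resp, alpha0)
    f0 = null_log_evidence(lme)
    # bor = 1 / (1 + exp(f1 - f0)), computed stably
    d = f1 - f0
    if d > 700.0:
        return 0.0
    if d < -700.0:
        return 1.0
    return float(1.0 / (1.0 + np.exp(d)))


def protected_xp(xp, bor: float, k: int | None = None) -> np.ndarray:
    """``pxp_k = (1 - bor) * xp_k + bor / K``."""
    xp = np.asarray(xp, dtype=float)
    if not 0.0 <= bor <= 1.0:
        raise ValueError(f"bor must be in [0,1], got {bor}")
    if k is None:
        k = len(xp)
    return (1.0 - bor) * xp + bor / k


def compare_models(log_evidence, model_labels=None, n_samples: int = 1_000_000,
                   seed: int = 0) -> BMSResult:
    """Full RFX-BMS pipeline: alpha, frequencies, XP, BOR, PXP."""
    lme = _check_matrix(log_evidence)
    alpha, freq, resp = rfx_bms(lme)
    xp = exceedance_probability(alpha, n_samples=n_samples, seed=seed)
    bor = bayes_omnibus_risk(lme, alpha=alpha, resp=resp)
    pxp = protected_xp(xp, bor)
    labels = tuple(model_labels) if model_labels is not None else None
    return BMSResult(alpha, freq, xp, bor, pxp, labels)
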