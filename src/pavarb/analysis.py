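"""Model-based behavioral analyses.

Go bias — accuracy on Go-required trials minus accuracy on
NoGo-required trials — is the behavioral fingerprint of Pavlovian
influence.  This module bins each subject's trials by within-subject
quantiles of the model's Pavlovian weight ``w``, computes the go bias
per bin and valence, tests the early vs late go bias, correlates ``w``
with the model's value traces (confound check, including a default JZS
Bayes factor for the null), and derives the expected-accuracy
confidence proxy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .task import GO, REQUIRED_ACTION, VALENCE


class DegenerateBinningError(ValueError):
    """Raised when a subject's w series is constant and cannot be binned."""


class UndefinedGoBiasError(ValueError):
    """Raised when a trial subset lacks Go-required or NoGo-required trials."""


# ---------------------------------------------------------------------------
# quantile binning and go bias
# ---------------------------------------------------------------------------

def assign_weight_quantiles(w, n_quantiles: int = 5) -> np.ndarray:
    """Within-subject rank-based quantile bins of the per-trial weight.

    Ties are broken by trial order (stable ranking), so bin sizes differ
    by at most one trial.  Returns integer bins ``0 .. n_quantiles-1``;
    the binning is invariant to strictly increasing transforms of *w*.
    """
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("w contains non-finite values")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if n_quantiles > len(w):
        raise ValueError("more quantiles than trials")
    if np.ptp(w) == 0:
        raise DegenerateBinningError("constant w: quantile bins undefined")
    ranks = np.argsort(np.argsort(w, kind="stable"), kind="stable")
    return (ranks * n_quantiles) // len(w)


def go_bias(records: pd.DataFrame) -> float:
    """accuracy(Go-required trials) - accuracy(NoGo-required trials)."""
    req = records["condition"].map(REQUIRED_ACTION)
    go_trials = records[req == GO]
    nogo_trials = records[req != GO]
    if len(go_trials) == 0 or len(nogo_trials) == 0:
        raise UndefinedGoBiasError(
            "go bias needs both Go-required and NoGo-required trials")
    return float(go_trials["correct"].mean() - nogo_trials["correct"].mean())


@dataclass
class QuantileGoBias:
    """Across-subject summary of go bias per weight quantile."""

    per_subject: pd.DataFrame       # subject_id, valence, bin, go_bias
    summary: pd.DataFrame           # valence, bin, mean, sem, n
    top_vs_bottom: dict             # valence -> {diff_mean, t, p, n}
    n_quantiles: int
    excluded_subjects: list


def go_bias_by_quantile(dataset, traces: dict, n_quantiles: int = 5) -> QuantileGoBias:
    """Per-bin, per-valence go bias with across-subject mean +- SEM.

    *traces* maps subject_id to a :class:`~pavarb.models.LatentTrace`
    aligned to that subject's trial order.  Subjects with a constant
    weight series are excluded with a warning.  A paired t-test compares
    top vs bottom bin within each valence.
    """
    rows, excluded = [], []
    for sid, sub in dataset.iter_subjects():
        trace = traces[sid]
        if len(trace) != len(sub):
            raise ValueError(f"trace for {sid} is not aligned to its trials")
        try:
            bins = assign_weight_quantiles(trace.w, n_quantiles)
        except DegenerateBinningError:
            warnings.warn(f"subject {sid}: constant w, excluded from binning")
            excluded.append(sid)
            continue
        sub = sub.assign(_bin=bins, _valence=sub["condition"].map(VALENCE))
        for (val, b), grp in sub.groupby(["_valence", "_bin"], sort=True):
            try:
                gb = go_bias(grp)
            except UndefinedGoBiasError:
                gb = np.nan
            rows.append((sid, val, int(b), gb))
    per_subject = pd.DataFrame(rows, columns=["subject_id", "valence",
                                              "bin", "go_bias"])
    summary = (per_subject.groupby(["valence", "bin"])["go_bias"]
               .agg(mean="mean", sem="sem", n="count").reset_index())
    tvb = {}
    for val, grp in per_subject.groupby("valence"):
        wide = grp.pivot(index="subject_id", columns="bin", values="go_bias")
        top, bot = wide.get(n_quantiles - 1), wide.get(0)
        if top is None or bot is None:
            continue
        paired = pd.concat([top, bot], axis=1).dropna()
        diff = paired.iloc[:, 0] - paired.iloc[:, 1]
        if len(diff) >= 2 and diff.std() > 0:
            t, p = stats.ttest_1samp(diff, 0.0)
        else:
            t, p = np.nan, np.nan
        tvb[val] = {"diff_mean": float(diff.mean()), "t": float(t),
                    "p": float(p), "n": int(len(diff))}
    return QuantileGoBias(per_subject, summary, tvb, n_quantiles, excluded)


# ---------------------------------------------------------------------------
# early vs late go bias
# ---------------------------------------------------------------------------

def early_late_go_bias(dataset, n_early: int = 40, n_late: int = 40,
                       conditions: str = "avoid") -> dict:
    """Go bias on the first *n_early* and last *n_late* trials of each
    subject's intermixed sequence, with one-sample t-tests against 0.

    *conditions* selects which trials count toward the go bias once the
    window is cut: ``"avoid"`` (default), ``"win"`` or ``"all"``.  The
    window itself is always positional within the full sequence.
    """
    if conditions not in ("avoid", "win", "all"):
        raise ValueError(f"bad conditions {conditions!r}")
    rows = []
    for sid, sub in dataset.iter_subjects():
        total = len(sub)
        if n_early + n_late > total:
            raise ValueError(
                f"subject {sid}: windows ({n_early}+{n_late}) exceed {total} trials")
        def _window_bias(win_df):
            if conditions != "all":
                win_df = win_df[win_df["condition"].map(VALENCE) == conditions]
            try:
                return go_bias(win_df)
            except UndefinedGoBiasError:
                return np.nan
        rows.append((sid,
                     _window_bias(sub[sub["trial_index"] < n_early]),
                     _window_bias(sub[sub["trial_index"] >= total - n_late])))
    per_subject = pd.DataFrame(rows, columns=["subject_id", "early", "late"])
    out = {"per_subject": per_subject, "conditions": conditions}
    for which in ("early", "late"):
        x = per_subject[which].dropna()
        if len(x) >= 2 and x.std() > 0:
            t, p = stats.ttest_1samp(x, 0.0)
        else:
            t, p = np.nan, np.nan
        out[which] = {"mean": float(x.mean()), "t": float(t), "p": float(p),
                      "n": int(len(x))}
    return out


# ---------------------------------------------------------------------------
# confound correlations and the JZS Bayes factor
# ---------------------------------------------------------------------------

def jzs_bayes_factor(x, scale: float = math.sqrt(2) / 2) -> float:
    """Default one-sample JZS Bayes factor BF01 (null over two-sided
    alternative) with a Cauchy prior of the given *scale* on effect size.

    The alternative's marginal likelihood is the 1-D integral over the
    Cauchy-distributed variance ratio ``g`` of the scaled t density;
    computed by adaptive quadrature.  BF01 > 1 favors the null.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        # all observations identical: t undefined unless the mean is 0,
        # in which case the null is supported maximally among t-tests
        if np.allclose(x.mean(), 0.0):
            return float("inf")
        return 0.0
    t = x.mean() / (sd / math.sqrt(n))
    return _jzs_bf01_from_t(t, n, scale)


def _jzs_bf01_from_t(t: float, n: int, scale: float) -> float:
    nu = n - 1
    null_like = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)

    def integrand(g):
        return ((1.0 + n * g * scale * scale) ** -0.5
                * (1.0 + t * t / ((1.0 + n * g * scale * scale) * nu))
                ** (-(nu + 1) / 2.0)
                * (2.0 * math.pi) ** -0.5 * g ** -1.5
                * math.exp(-1.0 / (2.0 * g)))

    alt_like, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(null_like / alt_like)


def fisher_z(r):
    """Fisher z-transform ``atanh(r)`` (clipped just inside +-1)."""
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r)


def confound_correlations(traces: dict,
                          variables=("v_inst_go", "v_inst_nogo", "v_pav")) -> dict:
    """Per-subject Pearson correlations of ``w`` with value traces.

    For each variable: per-subject r, the group median, a Wilcoxon
    signed-rank test of median 0, and the JZS Bayes factor BF01 on the
    Fisher z-transformed correlations.  Subjects with a zero-variance
    series are excluded with a warning.
    """
    out = {}
    for var in variables:
        rs = []
        for sid, trace in traces.items():
            w = np.asarray(trace.w, dtype=float)
            v = np.asarray(getattr(trace, var), dtype=float)
            if len(w) < 3:
                raise ValueError(f"subject {sid}: need >= 3 trials")
            if np.ptp(w) == 0 or np.ptp(v) == 0:
                warnings.warn(f"subject {sid}: zero variance in {var} or w; excluded")
                continue
            rs.append((sid, float(np.corrcoef(w, v)[0, 1])))
        per_subject = pd.DataFrame(rs, columns=["subject_id", "r"])
        r = per_subject["r"].to_numpy()
        res = {"per_subject": per_subject, "median_r": float(np.median(r))
               if len(r) else np.nan}
        if len(r) >= 2 and np.ptp(r) > 0:
            wstat, p = stats.wilcoxon(r)
            res["wilcoxon_p"] = float(p)
        else:
            res["wilcoxon_p"] = np.nan
        if len(r) >= 2:
            res["bf01"] = jzs_bayes_factor(fisher_z(r))
        else:
            res["bf01"] = np.nan
        out[var] = res
    return out


# ---------------------------------------------------------------------------
# expected accuracy (confidence proxy)
# ---------------------------------------------------------------------------

def expected_accuracy(trace, subject_trials: pd.DataFrame) -> np.ndarray:
    """Per-trial model probability of the optimal action:
    ``p_go`` on Go-required trials, ``1 - p_go`` on NoGo-required."""
    if len(trace) != len(subject_trials):
        raise ValueError("trace not aligned to trials")
    req = subject_trials["condition"].map(REQUIRED_ACTION).to_numpy()
    p_go = np.asarray(trace.p_go, dtype=float)
    return np.where(req == GO, p_go, 1.0 - p_go)
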