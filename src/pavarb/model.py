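"""Model/Results front end in the statsmodels idiom.

:class:`GoNoGoModel` is built from trial-level data; ``fit()`` runs the
per-subject maximum-likelihood estimation for each candidate learning
model and returns a :class:`GoNoGoResults` carrying the fitted
parameters, per-fit BIC evidences, the group-level RFX-BMS comparison,
latent traces at the fitted parameters, and a ``summary()`` table.

Example
-------
>>> from pavarb import GoNoGoModel, build_task_config, simulate_cohort
>>> # ... build or load a BehavioralDataset `data`
>>> res = GoNoGoModel(data).fit(n_restarts=10, seed=0)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analysis, bms, fitting, models
from .data import BehavioralDataset


class GoNoGoModel:
    """Competing learning models of one Go/NoGo dataset.

    Parameters
    ----------
    data : BehavioralDataset or DataFrame
        Trial-level records (see :class:`~pavarb.data.BehavioralDataset`).
    model_labels : sequence of str
        Candidate models to fit, among ``"rl"``, ``"fixed"``,
        ``"adaptive"``.
    """

    def __init__(self, data, model_labels=("rl", "fixed", "adaptive")):
        if isinstance(data, pd.DataFrame):
            data = BehavioralDataset(data)
        if not isinstance(data, BehavioralDataset):
            raise TypeError("data must be a BehavioralDataset or DataFrame")
        for lab in model_labels:
            if lab not in models.MODEL_LABELS:
                raise ValueError(f"unknown model {lab!r}")
        data.validate()
        self.data = data
        self.model_labels = tuple(model_labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GoNoGoModel":
        return cls(BehavioralDataset(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GoNoGoModel":
        return cls(BehavioralDataset.from_csv(path), **kwargs)

    def fit(self, n_restarts: int = 10, seed: int = 0,
            xp_samples: int = 1_000_000) -> "GoNoGoResults":
        """Fit every candidate model to every subject; compare at the
        group level when there are >= 2 candidates."""
        cohort = fitting.fit_cohort(self.data, self.model_labels,
                                    n_restarts=n_restarts, seed=seed)
        comparison = None
        if len(self.model_labels) >= 2:
            comparison = bms.compare_models(cohort.log_evidence_matrix(),
                                            model_labels=self.model_labels,
                                            n_samples=xp_samples, seed=seed)
        return GoNoGoResults(self, cohort, comparison)


class GoNoGoResults:
    """Fitted parameters, evidences and group-level comparison."""

    def __init__(self, model: GoNoGoModel, cohort: fitting.CohortFit,
                 comparison: bms.BMSResult | None):
        self.model = model
        self.cohort = cohort
        self.comparison = comparison

    @property
    def fits(self) -> pd.DataFrame:
        """One row per subject x model: parameters, nll, bic."""
        return self.cohort.table

    def params(self, subject_id, model_label):
        return self.cohort.result(subject_id, model_label).params

    def log_evidence_matrix(self) -> np.ndarray:
        return self.cohort.log_evidence_matrix()

    @property
    def pxp(self) -> dict:
        if self.comparison is None:
            raise ValueError("no model comparison (single candidate model)")
        return dict(zip(self.comparison.model_labels, self.comparison.pxp))

    def best_model(self) -> str:
        """Candidate with the highest protected exceedance probability."""
        pxp = self.pxp
        return max(pxp, key=pxp.get)

    def traces(self, model_label: str) -> dict:
        """Latent traces per subject at the fitted parameters."""
        out = {}
        for sid in self.cohort.subject_ids:
            stim, act, outc = self.model.data.arrays(sid)
            p = self.cohort.result(sid, model_label).params
            _, _, trace = models.run_model(stim, act, outc, model_label, p)
            out[sid] = trace
        return out

    def go_bias_by_quantile(self, model_label: str = "adaptive",
                            n_quantiles: int = 5) -> analysis.QuantileGoBias:
        return analysis.go_bias_by_quantile(self.model.data,
                                            self.traces(model_label),
                                            n_quantiles=n_quantiles)

    def summary(self) -> str:
        """Human-readable fit and comparison summary."""
        lines = ["Go/NoGo arbitration model comparison",
                 "=" * 52,
                 f"subjects: {self.model.data.n_subjects}   "
                 f"models: {', '.join(self.model.model_labels)}"]
        tab = self.fits.groupby("model").agg(
            mean_nll=("nll", "mean"), mean_bic=("bic", "mean"))
        lines.append("")
        lines.append(f"{'model':<10}{'mean NLL':>12}{'mean BIC':>12}"
                     f"{'PXP':>8}")
        for lab in self.model.model_labels:
            pxp = (f"{self.pxp[lab]:.3f}"
                   if self.comparison is not None else "   -")
            lines.append(f"{lab:<10}{tab.loc[lab, 'mean_nll']:>12.2f}"
                         f"{tab.loc[lab, 'mean_bic']:>12.2f}{pxp:>8}")
        if self.comparison is not None:
            lines.append("")
            lines.append(f"Bayes omnibus risk: {self.comparison.bor:.4f}")
            freqs = ", ".join(
                f"{lab}={f:.3f}" for lab, f in
                zip(self.comparison.model_labels,
                    self.comparison.expected_frequencies))
            lines.append(f"expected frequencies: {freqs}")
        return "\n".join(lines)

    def plot_go_bias_by_quantile(self, model_label: str = "adaptive",
                                 n_quantiles: int = 5, ax=None):
        """Go bias vs weight quantile, one line per valence."""
        import matplotlib.pyplot as plt

        qgb = self.go_bias_by_quantile(model_label, n_quantiles)
        if ax is None:
            _, ax = plt.subplots()
        for val, grp in qgb.summary.groupby("valence"):
            ax.errorbar(grp["bin"] + 1, grp["mean"], yerr=grp["sem"],
                        marker="o", capsize=3, label=val)
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("Pavlovian weight quantile")
        ax.set_ylabel("go bias")
        ax.legend(title="valence")
        return ax
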