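"""pavarb: Pavlovian-instrumental arbitration in the Go/NoGo task.

Simulation, maximum-likelihood fitting and group-level Bayesian
comparison of three learning models of Go/NoGo choice, plus the
model-based behavioral analyses (weight-quantile go bias, early/late go
bias, confound correlations, expected accuracy) and parameter/model
recovery experiments.
"""

from .task import TaskConfig, build_task_config, sample_outcome
from .data import BehavioralDataset
from .models import (
    RLParams, FixedBayesParams, AdaptiveBayesParams, LatentTrace,
    make_params, run_model,
)
from .simulate import simulate_subject, simulate_cohort

__version__ = "0.1.0"

__all__ = [
    "TaskConfig", "build_task_config", "sample_outcome",
    "BehavioralDataset", "LatentTrace",
    "RLParams", "FixedBayesParams", "AdaptiveBayesParams",
    "make_params", "run_model",
    "simulate_subject", "simulate_cohort",
    "GoNoGoModel",
]


def __getattr__(name):
    if name in ("GoNoGoModel", "GoNoGoResults"):
        from . import model

        return getattr(model, name)
    raise AttributeError(f"module 'pavarb' has no attribute {name!r}")
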