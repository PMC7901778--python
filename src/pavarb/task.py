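"""Go/NoGo task designs: conditions, outcome contingencies, sampling.

The task crosses outcome valence (Win a reward vs Avoid a punishment) with
the required response (Go = press, NoGo = withhold), yielding four
conditions, each signalled by its own stimulus.  The optimal action yields
the positive outcome (reward delivered on Win trials, punishment avoided on
Avoid trials) with probability ``p_optimal``; the suboptimal action with
probability ``1 - p_optimal``.  Outcomes are coded -1 (loss), 0 (neutral),
+1 (win).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GO = 1
NOGO = 0

CONDITIONS = ("go_win", "go_avoid", "nogo_win", "nogo_avoid")

#: required action per condition (1 = Go, 0 = NoGo)
REQUIRED_ACTION = {"go_win": GO, "go_avoid": GO, "nogo_win": NOGO, "nogo_avoid": NOGO}

#: valence per condition
VALENCE = {"go_win": "win", "go_avoid": "avoid", "nogo_win": "win", "nogo_avoid": "avoid"}

#: outcome values per valence: (positive outcome, negative outcome)
OUTCOME_MAGNITUDES = {"win": (1, 0), "avoid": (0, -1)}


class InvalidStudyError(ValueError):
    """Raised for an unrecognized study design label."""


@dataclass(frozen=True)
class TaskConfig:
    """Design of one Go/NoGo experiment.

    Parameters
    ----------
    trials_per_condition : int
        Number of trials for each of the four conditions.
    p_optimal : float
        Probability in (0.5, 1] that the optimal action yields the
        positive outcome.  The suboptimal action yields it with
        probability ``1 - p_optimal``.
    """

    trials_per_condition: int
    p_optimal: float
    conditions: tuple = field(default=CONDITIONS)

    def __post_init__(self):
        if not (0.5 < self.p_optimal <= 1.0):
            raise ValueError(f"p_optimal must be in (0.5, 1], got {self.p_optimal}")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be positive")
        if len(self.conditions) != 4:
            raise ValueError("a Go/NoGo design has exactly 4 conditions")

    @property
    def p_suboptimal(self) -> float:
        return 1.0 - self.p_optimal

    @property
    def n_trials(self) -> int:
        """Total trials per subject (4 x trials_per_condition)."""
        return 4 * self.trials_per_condition

    def to_dict(self) -> dict:
        return {
            "trials_per_condition": self.trials_per_condition,
            "p_optimal": self.p_optimal,
            "conditions": list(self.conditions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        kwargs = dict(d)
        if "conditions" in kwargs:
            kwargs["conditions"] = tuple(kwargs["conditions"])
        return cls(**kwargs)

    def to_file(self, path) -> None:
        """Write the design as a YAML key-value file."""
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_file(cls, path) -> "TaskConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: the two study designs this package emulates
STUDY_DESIGNS = {
    # EEG study: 40 trials/condition, 70/30 contingency
    "eeg": dict(trials_per_condition=40, p_optimal=0.7),
    # fMRI study: 60 trials/condition, 80/20 contingency
    "fmri": dict(trials_per_condition=60, p_optimal=0.8),
}


def build_task_config(study_label: str) -> TaskConfig:
    """Return the task design of one of the two reference studies.

    ``"eeg"`` gives 40 trials per condition with a 70/30 outcome
    contingency; ``"fmri"`` gives 60 trials per condition with 80/20.
    """
    try:
        kwargs = STUDY_DESIGNS[study_label]
    except KeyError:
        raise InvalidStudyError(
            f"unknown study {study_label!r}; expected one of {sorted(STUDY_DESIGNS)}"
        ) from None
    return TaskConfig(**kwargs)


def sample_outcome(condition: str, action: int, config: TaskConfig,
                   rng: np.random.Generator) -> int:
    """Sample one trial outcome.

    The positive outcome for the condition's valence occurs with
    probability ``p_optimal`` if *action* is the required action, else
    with probability ``p_suboptimal``.  Win conditions return +1 or 0,
    Avoid conditions return 0 or -1.
    """
    if condition not in config.conditions:
        raise ValueError(f"condition {condition!r} not in task config")
    p_pos = config.p_optimal if action == REQUIRED_ACTION[condition] else config.p_suboptimal
    pos, neg = OUTCOME_MAGNITUDES[VALENCE[condition]]
    return pos if rng.random() < p_pos else neg


def is_correct(condition: str, action: int) -> bool:
    """Whether *action* is the condition's required action."""
    return action == REQUIRED_ACTION[condition]
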