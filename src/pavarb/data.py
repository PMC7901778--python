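"""Trial-level behavioral datasets and their CSV representation.

A dataset is a thin wrapper around a pandas DataFrame with one row per
trial and columns ``subject_id, trial_index, condition, stimulus_id,
action, outcome, correct``.  Actions are stored as ``"go"`` / ``"nogo"``
in CSV and as integers (1 / 0) in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import CONDITIONS, GO, REQUIRED_ACTION, VALENCE, TaskConfig

COLUMNS = ["subject_id", "trial_index", "condition", "stimulus_id",
           "action", "outcome", "correct"]

#: fixed stimulus index per condition (one stimulus per condition)
STIMULUS_INDEX = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass
class BehavioralDataset:
    """Ordered trial records for one or more subjects.

    ``trials`` has the columns in :data:`COLUMNS`; within each subject
    ``trial_index`` runs 0..T-1 in presentation order.  ``metadata``
    records how synthetic data were generated (task config, seed, model,
    true parameters) and is empty for data loaded from disk.
    """

    trials: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        self.trials = self.trials.reset_index(drop=True)

    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.trials["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subject(self, subject_id) -> pd.DataFrame:
        """One subject's trials, ordered by trial_index."""
        df = self.trials[self.trials["subject_id"] == subject_id]
        if df.empty:
            raise KeyError(f"no such subject: {subject_id!r}")
        return df.sort_values("trial_index").reset_index(drop=True)

    def iter_subjects(self):
        for sid in self.subject_ids:
            yield sid, self.subject(sid)

    def arrays(self, subject_id):
        """(stimuli, actions, outcomes) integer arrays for one subject."""
        df = self.subject(subject_id)
        return (df["stimulus_id"].to_numpy(int),
                df["action"].to_numpy(int),
                df["outcome"].to_numpy(int))

    def validate(self, config: TaskConfig | None = None) -> None:
        """Check structural invariants; raise ValueError on violation."""
        df = self.trials
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValueError(f"unknown conditions: {set(df.loc[bad, 'condition'])}")
        valence = df["condition"].map(VALENCE)
        if ((valence == "win") & (df["outcome"] == -1)).any():
            raise ValueError("Win condition produced outcome -1")
        if ((valence == "avoid") & (df["outcome"] == 1)).any():
            raise ValueError("Avoid condition produced outcome +1")
        req = df["condition"].map(REQUIRED_ACTION)
        if not (df["correct"].astype(int) == (df["action"] == req).astype(int)).all():
            raise ValueError("'correct' column inconsistent with condition/action")
        for sid, sub in self.iter_subjects():
            t = sub["trial_index"].to_numpy()
            if not np.array_equal(np.sort(t), np.arange(len(sub))):
                raise ValueError(f"subject {sid}: trial_index is not 0..T-1")
            if config is not None:
                counts = sub["condition"].value_counts()
                for c in CONDITIONS:
                    if counts.get(c, 0) != config.trials_per_condition:
                        raise ValueError(
                            f"subject {sid}: condition {c} appears "
                            f"{counts.get(c, 0)} times, expected "
                            f"{config.trials_per_condition}")

    def to_csv(self, path) -> None:
        out = self.trials.copy()
        out["action"] = np.where(out["action"].astype(int) == GO, "go", "nogo")
        out["correct"] = out["correct"].astype(int)
        out[COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BehavioralDataset":
        df = pd.read_csv(path)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        action = df["action"]
        if action.dtype == object:
            lowered = action.str.lower()
            bad = ~lowered.isin(["go", "nogo"])
            if bad.any():
                raise ValueError(f"{path}: bad action codes {set(action[bad])}")
            df["action"] = (lowered == "go").astype(int)
        df["correct"] = df["correct"].astype(int)
        return cls(df)

    @classmethod
    def concat(cls, datasets, metadata=None) -> "BehavioralDataset":
        trials = pd.concat([d.trials for d in datasets], ignore_index=True)
        return cls(trials, metadata or {})
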