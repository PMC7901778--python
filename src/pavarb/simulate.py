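"""Forward simulation of Go/NoGo sessions from model-based agents.

Each simulated subject receives a fresh random permutation of the
condition multiset (conditions randomly intermixed, no run-length
constraints) and behaves according to one of the three learning models.
Action selection, outcome sampling and state updates reuse the exact
engines of :mod:`pavarb.models` and :mod:`pavarb.task`, so the
likelihood of a generating model evaluated on its own simulated data
reproduces the simulated latent trace bit for bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import models
from .data import COLUMNS, STIMULUS_INDEX, BehavioralDataset
from .task import CONDITIONS, GO, NOGO, TaskConfig, is_correct, sample_outcome


class EmptyCohortError(ValueError):
    """Raised when a cohort simulation is requested with no subjects."""


def condition_sequence(config: TaskConfig, rng: np.random.Generator) -> list[str]:
    """Random permutation of the full condition multiset."""
    seq = [c for c in CONDITIONS for _ in range(config.trials_per_condition)]
    perm = rng.permutation(len(seq))
    return [seq[i] for i in perm]


def simulate_subject(config: TaskConfig, model_label: str, params,
                     seed: int, subject_id="s0"):
    """Simulate one subject; returns ``(BehavioralDataset, LatentTrace)``.

    The agent samples Go with its current P(Go), the task samples an
    outcome, and the agent updates — the same code path used for
    likelihood evaluation.  Fully reproducible from *seed*.
    """
    rng = np.random.default_rng(seed)
    agent = models.make_agent(model_label, params)
    seq = condition_sequence(config, rng)
    T = len(seq)
    rows = []
    tr = {k: np.empty(T) for k in
          ("v_inst_go", "v_inst_nogo", "v_pav", "w", "p_go", "v_go", "v_nogo")}
    for t, cond in enumerate(seq):
        s = STIMULUS_INDEX[cond]
        st = agent.state
        w = agent.w
        v_go, v_nogo = agent.values(s)
        p = agent.p_go(s)
        action = GO if rng.random() < p else NOGO
        outcome = sample_outcome(cond, action, config, rng)
        tr["v_inst_go"][t] = st.v_inst[s][GO]
        tr["v_inst_nogo"][t] = st.v_inst[s][NOGO]
        tr["v_pav"][t] = st.v_pav[s]
        tr["w"][t] = np.nan if w is None else w
        tr["p_go"][t] = p
        tr["v_go"][t] = v_go
        tr["v_nogo"][t] = v_nogo
        rows.append((subject_id, t, cond, s, action, outcome,
                     int(is_correct(cond, action))))
        agent.update(s, action, outcome)
    trials = pd.DataFrame(rows, columns=COLUMNS)
    trace = models.LatentTrace(**{k: tr[k] for k in
                                  ("v_inst_go", "v_inst_nogo", "v_pav",
                                   "w", "p_go", "v_go", "v_nogo")})
    meta = {"config": config.to_dict(), "seed": int(seed),
            "model": model_label,
            "true_params": {subject_id: vars(params).copy()}}
    return BehavioralDataset(trials, meta), trace


def derive_subject_seed(master_seed: int, index: int) -> int:
    """Deterministic, collision-resistant per-subject seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def simulate_cohort(config: TaskConfig, model_label: str, params_per_subject,
                    seed: int, subject_ids=None, return_traces: bool = False):
    """Simulate independent subjects with per-subject derived seeds.

    ``params_per_subject`` is a list of parameter objects, one per
    subject.  Metadata stores every subject's true parameters.
    """
    params_per_subject = list(params_per_subject)
    if not params_per_subject:
        raise EmptyCohortError("params_per_subject must be non-empty")
    n = len(params_per_subject)
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(n)]
    datasets, traces, true_params = [], {}, {}
    for i, (sid, params) in enumerate(zip(subject_ids, params_per_subject)):
        d, tr = simulate_subject(config, model_label, params,
                                 derive_subject_seed(seed, i), subject_id=sid)
        datasets.append(d)
        traces[sid] = tr
        true_params[sid] = vars(params).copy()
    meta = {"config": config.to_dict(), "seed": int(seed),
            "model": model_label, "true_params": true_params}
    out = BehavioralDataset.concat(datasets, meta)
    return (out, traces) if return_traces else out
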