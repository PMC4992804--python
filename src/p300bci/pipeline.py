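"""End-to-end orchestration: session -> epochs -> features -> model -> modes.

This is the layer the CLI and the evaluation scripts drive.  It extracts the
per-trial epochs of a session, builds the subject template from labeled
training trials, assembles the training matrix, and runs a trained model
over a test session in any of the decision modes, producing a per-trial
outcome attribution that the session metrics are computed from.

Outcome attribution: every trial is credited to the decision event that
consumed it.  A command's correctness (against the truth at the trial where
it was emitted) is inherited by all trials accumulated into it; trials
consumed by an FM erase, by an illegal averaging block, or left pending at
session end count as non-recognition.  Experimental time is the full
elapsed session time (trials x 1.05 s), including non-recognized trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decision as dec
from .errors import InvalidParameterError
from .features import features_for_trial
from .metrics import ModeMetrics
from .network import NetworkModel, TrainingConfig, TrainingReport, train
from .paradigm import N_STIMULI
from .preprocess import Epoch, average_channels, extract_epochs
from .simulate import LabeledSession
from .template import TemplateP300, build_template

MODES = ("fm", "am", "avg1", "avg2", "avg3")


def session_epochs(session: LabeledSession, grid_snap: str = "up") -> list[list[Epoch]]:
    """Channel-average the recording and cut the four epochs of every trial."""
    signal = average_channels(session.recording, session.recording.channel_labels)
    fs = session.recording.sampling_rate
    return [
        extract_epochs(signal, onset, fs, trial_index=i, grid_snap=grid_snap)
        for i, onset in enumerate(session.schedule.trial_onsets)
    ]


def template_from_session(
    session: LabeledSession,
    n_epochs: int = 10,
    subject_id: str = "",
    trials: list[list[Epoch]] | None = None,
) -> TemplateP300:
    """Average the first ``n_epochs`` target-interval epochs into a template.

    Selection is automatic: the epochs at the known target interval of the
    labeled training trials, in trial order.
    """
    trials = trials if trials is not None else session_epochs(session)
    target_epochs = [
        trial[session.truth[i]] for i, trial in enumerate(trials)
    ][: max(1, n_epochs)]
    return build_template(target_epochs, subject_id=subject_id)


def training_matrix(
    session: LabeledSession,
    template: TemplateP300,
    trials: list[list[Epoch]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix X (4 rows per trial) and 0/1 target vector T."""
    trials = trials if trials is not None else session_epochs(session)
    rows, targets = [], []
    for i, trial in enumerate(trials):
        for feat in features_for_trial(trial, template):
            rows.append(feat.r)
            targets.append(1.0 if feat.interval_index == session.truth[i] else 0.0)
    return np.stack(rows), np.asarray(targets)


def train_pipeline(
    session: LabeledSession,
    config: TrainingConfig | None = None,
    n_template_epochs: int = 10,
    subject_id: str = "",
) -> tuple[NetworkModel, TrainingReport]:
    """Template building plus network training from one labeled session."""
    trials = session_epochs(session)
    template = template_from_session(session, n_template_epochs, subject_id, trials)
    X, T = training_matrix(session, template, trials)
    return train(X, T, config, template=template)


# ---------------------------------------------------------------------------
# mode runners


@dataclass
class ModeRun:
    """Decision log and per-trial outcome attribution of one mode run."""

    mode: str
    log: pd.DataFrame                    # one row per trial
    outcomes: list[str]                  # per trial: correct | wrong | non_recognition
    commands: list[tuple[int, int, bool]]  # (trial emitted, selected, correct)

    def metrics(self, trial_duration_s: float = 1.05) -> ModeMetrics:
        n = len(self.outcomes)
        n_corr_cmd = sum(1 for _, _, ok in self.commands if ok)
        return ModeMetrics(
            n_trials=n,
            correct=self.outcomes.count("correct"),
            wrong=self.outcomes.count("wrong"),
            non_recognition=self.outcomes.count("non_recognition"),
            t_exp=n * trial_duration_s,
            n_correct_commands=n_corr_cmd,
            n_wrong_commands=len(self.commands) - n_corr_cmd,
        )


def _log_row(i, d: dec.TrialDecision, event, selected):
    return {
        "trial": i,
        "status": d.status,
        "score_1": d.scores[0],
        "score_2": d.scores[1],
        "score_3": d.scores[2],
        "score_4": d.scores[3],
        "event": event or "",
        "selected": "" if selected is None else selected + 1,
    }


def _finish(mode, rows, outcomes, commands, n_trials):
    # trailing trials not consumed by any decision event
    outcomes.extend(["non_recognition"] * (n_trials - len(outcomes)))
    return ModeRun(mode=mode, log=pd.DataFrame(rows), outcomes=outcomes, commands=commands)


def run_fm(trials: list[list[Epoch]], truth: list[int], model: NetworkModel) -> ModeRun:
    state = dec.FMState()
    rows, outcomes, commands = [], [], []
    pending = 0
    for i, trial in enumerate(trials):
        pending += 1
        state, d, event = dec.fm_step(state, trial, model, trial_index=i)
        rows.append(_log_row(i, d, event, d.selected if event == "command" else None))
        if event == "command":
            ok = d.selected == truth[i]
            outcomes.extend(["correct" if ok else "wrong"] * pending)
            commands.append((i, d.selected, ok))
            pending = 0
        elif event == "erase":
            outcomes.extend(["non_recognition"] * pending)
            pending = 0
    return _finish("fm", rows, outcomes, commands, len(trials))


def run_am(trials: list[list[Epoch]], truth: list[int], model: NetworkModel) -> ModeRun:
    state = dec.AMState()
    rows, outcomes, commands = [], [], []
    pending = 0
    for i, trial in enumerate(trials):
        pending += 1
        d = dec.judge_trial(dec.score_epochs(model, trial), model.threshold, i)
        decided = None
        if d.is_legal:
            state, decided = dec.am_step(state, d.selected)
        rows.append(_log_row(i, d, "command" if decided is not None else None, decided))
        if decided is not None:
            ok = decided == truth[i]
            outcomes.extend(["correct" if ok else "wrong"] * pending)
            commands.append((i, decided, ok))
            pending = 0
    return _finish("am", rows, outcomes, commands, len(trials))


def run_avg(
    trials: list[list[Epoch]], truth: list[int], model: NetworkModel, n_avg: int
) -> ModeRun:
    decisions = dec.averaging_baseline(trials, n_avg, model)
    rows, outcomes, commands = [], [], []
    for d in decisions:
        event = "command" if d.is_legal else "non_recognition"
        rows.append(_log_row(d.trial_index, d, event, d.selected))
        if d.is_legal:
            ok = d.selected == truth[d.trial_index]
            outcomes.extend(["correct" if ok else "wrong"] * n_avg)
            commands.append((d.trial_index, d.selected, ok))
        else:
            outcomes.extend(["non_recognition"] * n_avg)
    return _finish(f"avg{n_avg}", rows, outcomes, commands, len(trials))


def run_mode(
    session: LabeledSession, model: NetworkModel, mode: str,
    trials: list[list[Epoch]] | None = None,
) -> ModeRun:
    """Run one decision mode over a session."""
    if mode not in MODES:
        raise InvalidParameterError(f"mode must be one of {MODES}")
    trials = trials if trials is not None else session_epochs(session)
    if mode == "fm":
        return run_fm(trials, session.truth, model)
    if mode == "am":
        return run_am(trials, session.truth, model)
    return run_avg(trials, session.truth, model, int(mode[-1]))


def single_epoch_accuracy(
    trials: list[list[Epoch]], truth: list[int], model: NetworkModel
) -> float:
    """Fraction of trials whose single-epoch judgement is legal and correct."""
    hits = 0
    for i, trial in enumerate(trials):
        d = dec.judge_trial(dec.score_epochs(model, trial), model.threshold, i)
        if d.is_legal and d.selected == truth[i]:
            hits += 1
    return hits / len(trials)
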