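"""Trial-level decision logic: legal-trial rule, FM accumulation, AM voting.

A trial is *legal* when exactly one of the four network outputs exceeds the
threshold; zero or multiple super-threshold outputs make it illegal.

Fast-recognition mode (FM) decides from the latest legal trial; on an
illegal trial it stores the raw epochs and averages them with the next
trial's, up to 5, then erases and reports a non-recognition.

Accuracy-recognition mode (AM) is a voting automaton over legal trials: a
command is issued when the same label occurs twice among the last three
legal trials; three distinct labels drop the oldest and the vote continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .features import timeshift_features
from .network import DEFAULT_THRESHOLD, NetworkModel, forward
from .paradigm import COMMANDS, N_STIMULI
from .preprocess import CONTEXT_SAMPLES, Epoch, epoch_from_context

#: FM gives up after this many accumulated trials
FM_MAX_EPOCHS = 5
#: AM vote: a label must occur this many times among the tracked legal trials
AM_VOTES_NEEDED = 2
#: AM vote window: "the last three legal trials"
AM_WINDOW = 3


@dataclass(frozen=True)
class TrialDecision:
    """Outcome of the legal-trial rule for one (possibly averaged) trial."""

    trial_index: int
    scores: tuple[float, float, float, float]
    status: str                      # "legal" | "illegal_multiple" | "illegal_none"
    selected: int | None             # 0-based stimulus index when legal

    @property
    def is_legal(self) -> bool:
        return self.status == "legal"

    @property
    def selected_ordinal(self) -> int | None:
        """1-based stimulus ordinal, as in "the second stimulus"."""
        return None if self.selected is None else self.selected + 1

    @property
    def command(self) -> str | None:
        return None if self.selected is None else COMMANDS[self.selected]


def judge_trial(
    scores, threshold: float = DEFAULT_THRESHOLD, trial_index: int = 0
) -> TrialDecision:
    """Apply the legal-trial rule: exactly one score strictly above threshold."""
    scores = [float(s) for s in scores]
    if len(scores) != N_STIMULI:
        raise InvalidParameterError(f"expected {N_STIMULI} scores, got {len(scores)}")
    above = [k for k, s in enumerate(scores) if s > threshold]
    if len(above) == 1:
        return TrialDecision(trial_index, tuple(scores), "legal", above[0])
    status = "illegal_none" if not above else "illegal_multiple"
    return TrialDecision(trial_index, tuple(scores), status, None)


def score_epochs(model: NetworkModel, epochs: list[Epoch]) -> np.ndarray:
    """Network score per interval: featurize each epoch against the template."""
    if model.template is None:
        raise InvalidParameterError("model has no P300 template")
    feats = np.stack([timeshift_features(ep, model.template).r for ep in epochs])
    return np.asarray(forward(model, feats))


# ---------------------------------------------------------------------------
# fast-recognition mode


@dataclass
class FMState:
    """Running per-interval epoch sums of the FM accumulator."""

    epoch_sums: np.ndarray = field(
        default_factory=lambda: np.zeros((N_STIMULI, CONTEXT_SAMPLES))
    )
    n_accumulated: int = 0


def fm_step(
    state: FMState,
    trial_epochs: list[Epoch],
    model: NetworkModel,
    trial_index: int = 0,
) -> tuple[FMState, TrialDecision, str | None]:
    """Advance FM by one trial.

    Raw epoch contexts are added to the per-interval sums and the averaged
    epochs are renormalized, featurized and classified.  A legal result
    emits ``"command"`` and resets the accumulator; an illegal result at the
    5th accumulated trial emits ``"erase"`` (non-recognition) and resets;
    otherwise the state carries forward and the event is ``None``.
    """
    if len(trial_epochs) != N_STIMULI:
        raise InvalidParameterError(f"expected {N_STIMULI} epochs per trial")
    sums = state.epoch_sums + np.stack([ep.context for ep in trial_epochs])
    n = state.n_accumulated + 1
    averaged = [
        epoch_from_context(
            sums[k] / n,
            trial_index=trial_index,
            interval_index=k,
            start_offset_ms=trial_epochs[k].start_offset_ms,
        )
        for k in range(N_STIMULI)
    ]
    decision = judge_trial(score_epochs(model, averaged), model.threshold, trial_index)
    if decision.is_legal:
        return FMState(), decision, "command"
    if n >= FM_MAX_EPOCHS:
        return FMState(), decision, "erase"
    return FMState(epoch_sums=sums, n_accumulated=n), decision, None


# ---------------------------------------------------------------------------
# accuracy-recognition mode


@dataclass(frozen=True)
class AMState:
    """Pending legal-trial labels of the voting automaton (at most 2)."""

    vote_window: tuple[int, ...] = ()


def am_step(state: AMState, legal_label: int) -> tuple[AMState, int | None]:
    """Advance the AM voting automaton by one *legal* trial.

    Returns the new state and the decided label, or ``None`` while the vote
    is still open.  Illegal trials never reach this function.
    """
    if not 0 <= legal_label < N_STIMULI:
        raise InvalidParameterError(f"label {legal_label} outside 0..{N_STIMULI - 1}")
    window = state.vote_window + (legal_label,)
    # a label repeated among the last three legal trials wins
    if window.count(legal_label) >= AM_VOTES_NEEDED:
        return AMState(), legal_label
    if len(window) >= AM_WINDOW:
        # three distinct labels: abandon the oldest, keep voting
        window = window[1:]
    return AMState(vote_window=window), None


# ---------------------------------------------------------------------------
# fixed-n averaging baseline


def averaging_baseline(
    trials: list[list[Epoch]],
    n_avg: int,
    model: NetworkModel,
) -> list[TrialDecision]:
    """Classify non-overlapping blocks of ``n_avg`` trials by epoch averaging.

    Each complete block yields one decision (legal command or illegal
    non-recognition); there is no carry-over between blocks, and a trailing
    incomplete block yields nothing.  The decision's ``trial_index`` is the
    last trial of its block.
    """
    if n_avg not in (1, 2, 3):
        raise InvalidParameterError("n_avg must be 1, 2 or 3")
    decisions = []
    for start in range(0, len(trials) - n_avg + 1, n_avg):
        block = trials[start : start + n_avg]
        sums = np.zeros((N_STIMULI, CONTEXT_SAMPLES))
        for trial_epochs in block:
            sums += np.stack([ep.context for ep in trial_epochs])
        averaged = [
            epoch_from_context(
                sums[k] / n_avg,
                trial_index=start + n_avg - 1,
                interval_index=k,
                start_offset_ms=block[0][k].start_offset_ms,
            )
            for k in range(N_STIMULI)
        ]
        decisions.append(
            judge_trial(score_epochs(model, averaged), model.threshold, start + n_avg - 1)
        )
    return decisions
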