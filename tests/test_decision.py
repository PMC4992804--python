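import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import p300bci as p
from p300bci import decision as dec
from p300bci.errors import InvalidParameterError
from p300bci.network import NetworkModel


class TestJudgeTrial:
    def test_printed_worked_example_selects_second_stimulus(self):
        d = p.judge_trial([0.2910, 0.9473, 0.2493, 0.0233], threshold=0.6)
        assert d.status == "legal"
        assert d.selected == 1
        assert d.selected_ordinal == 2
        assert d.command == "right-turn"

    def test_multiple_targets_illegal(self):
        d = p.judge_trial([0.7, 0.8, 0.1, 0.1])
        assert d.status == "illegal_multiple" and d.selected is None

    def test_no_targets_illegal(self):
        d = p.judge_trial([0.1, 0.2, 0.3, 0.4])
        assert d.status == "illegal_none" and d.selected is None

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=4, max_size=4))
    def test_legal_iff_exactly_one_above_threshold(self, scores):
        d = p.judge_trial(scores, threshold=0.6)
        n_above = sum(1 for s in scores if s > 0.6)
        assert d.is_legal == (n_above == 1)
        assert (d.selected is not None) == d.is_legal


def reference_am(labels):
    """Literal route-based transcription of the voting rules.

    Two equal legal trials decide (route a); on a tie-break round the third
    trial decides if it matches either pending label (routes b, c); three
    distinct labels abandon the oldest and the vote continues (route d).
    """
    decisions = []
    pending = []
    for i, x in enumerate(labels):
        pending.append(x)
        if len(pending) == 2:
            if pending[0] == pending[1]:
                decisions.append((i, pending[0]))
                pending = []
        elif len(pending) == 3:
            a, b, c = pending
            if c == a:
                decisions.append((i, a))
                pending = []
            elif c == b:
                decisions.append((i, b))
                pending = []
            else:
                pending = [b, c]
    return decisions


def run_am(labels):
    state = p.AMState()
    out = []
    for i, lab in enumerate(labels):
        state, decided = p.am_step(state, lab)
        if decided is not None:
            out.append((i, decided))
    return out


class TestAmVoting:
    def test_route_a_immediate_repeat(self):
        assert run_am([0, 0]) == [(1, 0)]

    def test_route_b_first_label_returns(self):
        assert run_am([0, 1, 0]) == [(2, 0)]

    def test_route_c_second_label_repeats(self):
        assert run_am([0, 1, 1]) == [(2, 1)]

    def test_route_d_then_repeat(self):
        assert run_am([0, 1, 2, 2]) == [(3, 2)]

    def test_never_decides_from_single_trial(self):
        state = p.AMState()
        state, decided = p.am_step(state, 3)
        assert decided is None

    def test_window_never_exceeds_two_between_decisions(self):
        rng = np.random.default_rng(0)
        state = p.AMState()
        for lab in rng.integers(0, 4, size=500):
            state, _ = p.am_step(state, int(lab))
            assert len(state.vote_window) <= 2

    def test_exhaustive_equivalence_with_route_reference(self):
        """All 4^6 label sequences: automaton == verbal-rule transcription."""
        for labels in itertools.product(range(4), repeat=6):
            assert run_am(labels) == reference_am(labels), labels

    def test_invalid_label(self):
        with pytest.raises(InvalidParameterError):
            p.am_step(p.AMState(), 4)


def constant_score_model(value, threshold=0.6):
    """A network whose output is ``value`` for any input (all weights zero)."""
    tpl = p.build_template([p.p300_waveform(216, 1.0, 280)])
    return NetworkModel(w=np.zeros((15, 31)), b=np.zeros(15), hw=np.zeros(15),
                        ob=value, threshold=threshold, template=tpl)


def noise_trial(rng, trial_index=0):
    from p300bci.preprocess import epoch_from_context

    return [
        epoch_from_context(rng.normal(size=100), trial_index, k) for k in range(4)
    ]


class TestFmAccumulation:
    def test_erase_exactly_at_fifth_consecutive_illegal(self, rng):
        model = constant_score_model(0.0)  # every trial illegal_none
        state = p.FMState()
        events = []
        for i in range(15):
            state, d, event = p.fm_step(state, noise_trial(rng, i), model, i)
            events.append(event)
            assert state.n_accumulated <= 5
        assert events == [None, None, None, None, "erase"] * 3

    def test_illegal_multiple_also_accumulates(self, rng):
        model = constant_score_model(0.9)  # every interval above threshold
        state = p.FMState()
        events = []
        for i in range(5):
            state, d, event = p.fm_step(state, noise_trial(rng, i), model, i)
            assert d.status == "illegal_multiple"
            events.append(event)
        assert events == [None, None, None, None, "erase"]

    def test_legal_first_trial_emits_immediately(self, trained_setup):
        model = trained_setup["model"]
        trials = trained_setup["test_trials"]
        truth = trained_setup["test_session"].truth
        # find a trial that is legal on its own and feed it to a fresh FM state
        for i, trial in enumerate(trials):
            d = p.judge_trial(dec.score_epochs(model, trial), model.threshold)
            if d.is_legal:
                state, d2, event = p.fm_step(p.FMState(), trial, model, i)
                assert event == "command"
                assert d2.selected == d.selected
                assert state.n_accumulated == 0
                break
        else:
            pytest.fail("no legal single trial found in the test session")

    def test_accumulation_recovers_weak_trials(self):
        """A session too noisy for some single trials still yields commands
        through epoch accumulation, and FM emits at most one command per trial."""
        from helpers import make_session

        session = make_session(40, seed=77, noise_sd=16.0)
        trials = p.session_epochs(session)
        from p300bci.pipeline import train_pipeline

        train_sess = make_session(120, seed=78, noise_sd=16.0)
        model, _ = train_pipeline(train_sess, p.TrainingConfig(seed=79))
        state = p.FMState()
        n_commands = n_from_accumulation = 0
        for i, trial in enumerate(trials):
            n_before = state.n_accumulated
            state, d, event = p.fm_step(state, trial, model, i)
            if event == "command":
                n_commands += 1
                if n_before > 0:
                    n_from_accumulation += 1
        assert n_commands > 0
        assert n_from_accumulation > 0  # some commands needed > 1 epoch


class TestAveragingBaseline:
    def test_n1_matches_judge_trial(self, trained_setup):
        model = trained_setup["model"]
        trials = trained_setup["test_trials"][:10]
        decisions = p.averaging_baseline(trials, 1, model)
        for i, d in enumerate(decisions):
            direct = p.judge_trial(
                dec.score_epochs(model, trials[i]), model.threshold, i
            )
            assert d.status == direct.status and d.selected == direct.selected

    def test_block_count(self, trained_setup):
        model = trained_setup["model"]
        trials = trained_setup["test_trials"]
        assert len(p.averaging_baseline(trials, 3, model)) == len(trials) // 3

    def test_invalid_n_avg(self, trained_setup):
        with pytest.raises(InvalidParameterError):
            p.averaging_baseline(trained_setup["test_trials"], 4, trained_setup["model"])
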