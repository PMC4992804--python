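"""Shared builders for the test suite."""

import p300bci as p


def make_session(n_trials: int, seed: int, **overrides) -> p.LabeledSession:
    """A session under the default study conditions with a blocked truth sequence."""
    cfg = p.SimulationConfig(
        target_sequence=p.blocked_targets(n_trials, 5, seed=seed),
        seed=seed,
        **overrides,
    )
    return p.simulate_session(cfg)
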