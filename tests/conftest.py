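import numpy as np
import pytest

import p300bci as p
from helpers import make_session


@pytest.fixture(scope="session")
def trained_setup():
    """A model trained on a 160-trial session plus a held-out 100-trial session.

    Session-scoped: training runs once and is shared by the classification,
    decision-mode and acceptance tests.
    """
    train_session = make_session(160, seed=1000)
    model, report = p.train_pipeline(train_session, p.TrainingConfig(seed=1001))
    test_session = make_session(100, seed=1100)
    test_trials = p.session_epochs(test_session)
    return {
        "model": model,
        "report": report,
        "train_session": train_session,
        "test_session": test_session,
        "test_trials": test_trials,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
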