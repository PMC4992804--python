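"""The 31-15-1 feedforward network and its backpropagation trainer.

Architecture: 31 inputs (the time-shift correlations), one hidden layer of
15 tanh-sigmoid units, and a single *linear* output unit — the output is not
squashed, which is why trained scores such as 0.0233 or 0.9473 fall freely
around the 0/1 training targets.  The parameter count is
m*(n+2)+1 = 496 for n=31, m=15.  Training is batch gradient descent on the
mean squared error with optional momentum and early stopping on a held-out
stop partition.  The early-stop patience defaults to 2000 epochs:
plain batch gradient descent produces a transient hump in the stop-partition
error during its early plateau, and a short patience window aborts training
inside that hump long before convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, LengthError
from .paradigm import N_SHIFTS
from .template import TemplateP300

DEFAULT_HIDDEN = 15
DEFAULT_THRESHOLD = 0.6


@dataclass
class NetworkModel:
    """Weights, biases, decision threshold, and the subject's template."""

    w: np.ndarray          # hidden weights, m x n
    b: np.ndarray          # hidden biases, m
    hw: np.ndarray         # hidden-to-output weights, m
    ob: float              # output bias
    threshold: float = DEFAULT_THRESHOLD
    template: TemplateP300 | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.hw = np.asarray(self.hw, dtype=float)
        if self.w.ndim != 2:
            raise InvalidParameterError("w must be m x n")
        m, _ = self.w.shape
        if self.b.shape != (m,) or self.hw.shape != (m,):
            raise InvalidParameterError("b and hw must have one entry per hidden unit")

    @property
    def n(self) -> int:
        return self.w.shape[1]

    @property
    def m(self) -> int:
        return self.w.shape[0]

    @property
    def n_parameters(self) -> int:
        """m*(n+2)+1: hidden weights + hidden biases + output weights + output bias."""
        return self.m * (self.n + 2) + 1


def init_model(
    n: int = N_SHIFTS,
    m: int = DEFAULT_HIDDEN,
    seed: int | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    template: TemplateP300 | None = None,
) -> NetworkModel:
    """Seeded uniform initialization scaled by layer fan-in."""
    rng = np.random.default_rng(seed)
    lim_w = 1.0 / np.sqrt(n)
    lim_hw = 1.0 / np.sqrt(m)
    return NetworkModel(
        w=rng.uniform(-lim_w, lim_w, size=(m, n)),
        b=rng.uniform(-lim_w, lim_w, size=m),
        hw=rng.uniform(-lim_hw, lim_hw, size=m),
        ob=float(rng.uniform(-lim_hw, lim_hw)),
        threshold=threshold,
        template=template,
    )


def _tanh_sigmoid(n: np.ndarray) -> np.ndarray:
    # f(N) = 2 / (1 + exp(-2N)) - 1, identical to tanh(N)
    return np.tanh(n)


def forward(model: NetworkModel, x: np.ndarray) -> float | np.ndarray:
    """Network output for one feature vector (or a batch, rows = examples)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n:
        raise LengthError(f"input has {X.shape[1]} features, model expects {model.n}")
    H = _tanh_sigmoid(X @ model.w.T + model.b)
    y = H @ model.hw + model.ob
    return float(y[0]) if single else y


def classify_interval(model: NetworkModel, x: np.ndarray) -> tuple[float, bool]:
    """Score one interval and apply the threshold (strict >)."""
    score = forward(model, x)
    return score, bool(score > model.threshold)


@dataclass
class TrainingConfig:
    """Hyperparameters of the backpropagation run."""

    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 9000
    mse_goal: float = 1e-5
    learning_rate: float = 0.01
    momentum: float = 0.0
    patience: int = 2000
    hidden: int = DEFAULT_HIDDEN
    seed: int | None = None
    checkpoint_every: int = 100

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise InvalidParameterError("split fractions must sum to 1")
        if any(f < 0 for f in self.split):
            raise InvalidParameterError("split fractions must be non-negative")
        if self.max_epochs < 0 or self.learning_rate <= 0:
            raise InvalidParameterError("max_epochs >= 0 and learning_rate > 0 required")


@dataclass
class TrainingReport:
    """What the trainer did: epochs run, stop reason, per-partition errors."""

    epochs_run: int
    stop_reason: str
    mse_train: float
    mse_test: float
    mse_stop: float
    checkpoints: list[tuple[int, float]] = field(default_factory=list)


def _partition(n_examples: int, split: tuple[float, float, float], rng) -> tuple:
    idx = rng.permutation(n_examples)
    n_train = int(round(split[0] * n_examples))
    n_test = int(round(split[1] * n_examples))
    train = idx[:n_train]
    test = idx[n_train : n_train + n_test]
    stop = idx[n_train + n_test :]
    return train, test, stop


def _mse(model: NetworkModel, X: np.ndarray, T: np.ndarray) -> float:
    y = forward(model, X)
    return float(np.mean((T - y) ** 2))


def train(
    X: np.ndarray,
    T: np.ndarray,
    config: TrainingConfig | None = None,
    template: TemplateP300 | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[NetworkModel, TrainingReport]:
    """Train the network on (feature vector, 0/1 target) pairs.

    The dataset is split 70/15/15 into training, generalization-test and
    early-stop partitions (seeded shuffle).  Batch gradient descent runs on
    the training MSE until ``max_epochs``, until the goal MSE is reached, or
    until the stop-partition MSE has not improved for ``patience`` epochs,
    in which case the best-so-far weights are restored.  Deterministic for a
    fixed seed.
    """
    config = config or TrainingConfig()
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != T.size:
        raise InvalidParameterError("X must be examples x features matching T")
    rng = np.random.default_rng(config.seed)
    tr, te, st = _partition(X.shape[0], config.split, rng)
    if len(tr) == 0 or (config.split[1] > 0 and len(te) == 0) or (
        config.split[2] > 0 and len(st) == 0
    ):
        raise InvalidParameterError("degenerate split: a requested partition is empty")
    Xtr, Ttr = X[tr], T[tr]
    Xst, Tst = (X[st], T[st]) if len(st) else (Xtr, Ttr)

    model = init_model(
        n=X.shape[1], m=config.hidden,
        seed=int(rng.integers(2**31)), threshold=threshold, template=template,
    )
    p = Xtr.shape[0]
    vel = [np.zeros_like(model.w), np.zeros_like(model.b), np.zeros_like(model.hw), 0.0]
    best = (model.w.copy(), model.b.copy(), model.hw.copy(), model.ob)
    best_stop = _mse(model, Xst, Tst)
    since_best = 0
    checkpoints: list[tuple[int, float]] = [(0, _mse(model, Xtr, Ttr))]
    stop_reason = "max_epochs"
    epochs_run = 0

    if checkpoints[0][1] <= config.mse_goal:
        stop_reason = "mse_goal"
    else:
        for epoch in range(1, config.max_epochs + 1):
            H = _tanh_sigmoid(Xtr @ model.w.T + model.b)
            y = H @ model.hw + model.ob
            err = y - Ttr
            dy = 2.0 * err / p                     # d(MSE)/dy
            g_hw = H.T @ dy
            g_ob = float(dy.sum())
            dN = np.outer(dy, model.hw) * (1.0 - H**2)
            g_w = dN.T @ Xtr
            g_b = dN.sum(axis=0)

            lr, mom = config.learning_rate, config.momentum
            vel[0] = mom * vel[0] - lr * g_w
            vel[1] = mom * vel[1] - lr * g_b
            vel[2] = mom * vel[2] - lr * g_hw
            vel[3] = mom * vel[3] - lr * g_ob
            model.w += vel[0]
            model.b += vel[1]
            model.hw += vel[2]
            model.ob += vel[3]
            epochs_run = epoch

            mse_tr = _mse(model, Xtr, Ttr)
            if epoch % config.checkpoint_every == 0 or epoch == config.max_epochs:
                checkpoints.append((epoch, mse_tr))
            if mse_tr <= config.mse_goal:
                stop_reason = "mse_goal"
                break
            mse_st = _mse(model, Xst, Tst)
            if mse_st < best_stop - 1e-12:
                best_stop = mse_st
                best = (model.w.copy(), model.b.copy(), model.hw.copy(), model.ob)
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    stop_reason = "early_stop"
                    model.w, model.b, model.hw, model.ob = (
                        best[0].copy(), best[1].copy(), best[2].copy(), best[3],
                    )
                    break

    report = TrainingReport(
        epochs_run=epochs_run,
        stop_reason=stop_reason,
        mse_train=_mse(model, Xtr, Ttr),
        mse_test=_mse(model, X[te], T[te]) if len(te) else float("nan"),
        mse_stop=_mse(model, Xst, Tst),
        checkpoints=checkpoints,
    )
    return model, report


def threshold_diagnostic(
    model: NetworkModel,
    X: np.ndarray,
    targets: np.ndarray,
    n_trials: int = 20,
    seed: int | None = None,
) -> dict:
    """Inspect trained outputs on a random subset of labeled examples.

    Reproduces the manual threshold-selection procedure: score a random
    sample, summarize target and non-target output ranges, and report the
    midpoint gap.  The returned dict is a report, not an optimizer — the
    operating threshold stays an explicit choice (0.6 by default).
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets).astype(bool).ravel()
    rng = np.random.default_rng(seed)
    take = rng.choice(X.shape[0], size=min(4 * n_trials, X.shape[0]), replace=False)
    y = forward(model, X[take])
    lab = targets[take]
    t_scores = y[lab]
    n_scores = y[~lab]
    return {
        "n_scored": int(take.size),
        "target_min": float(t_scores.min()) if t_scores.size else float("nan"),
        "target_median": float(np.median(t_scores)) if t_scores.size else float("nan"),
        "nontarget_max": float(n_scores.max()) if n_scores.size else float("nan"),
        "nontarget_median": float(np.median(n_scores)) if n_scores.size else float("nan"),
        "suggested_threshold": float((np.median(t_scores) + np.median(n_scores)) / 2)
        if t_scores.size and n_scores.size
        else float("nan"),
        "configured_threshold": float(model.threshold),
    }
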