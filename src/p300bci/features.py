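"""Time-shift Pearson correlation features.

The P300 peak latency varies by tens of milliseconds from trial to trial, so
a single correlation against the template can miss a genuine response.  The
acquisition window is therefore slid from -60 ms to +60 ms in 4 ms steps
(one sample at 250 Hz) over the epoch's raw context; each 70-sample slice is
min-max normalized and correlated with the template.  A matched epoch yields
a bell-shaped 31-point correlation curve whose peak position reveals the
latency offset; a mismatched epoch yields an irregular low-amplitude curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, LengthError
from .paradigm import N_SHIFTS, SHIFT_STEP_MS
from .preprocess import CONTEXT_MARGIN, EPOCH_SAMPLES, Epoch, normalize01
from .template import TemplateP300

#: shift of feature i (0-based), in ms: -60, -56, ..., +60
SHIFTS_MS = (np.arange(N_SHIFTS) - CONTEXT_MARGIN) * SHIFT_STEP_MS


@dataclass
class FeatureVector:
    """31 time-shift correlations for one stimulus interval.

    ``r[i]`` is the correlation at a shift of ``(i - 15) * 4`` ms (0-based
    index; the centre element r[15] is the unshifted correlation).
    """

    r: np.ndarray
    interval_index: int = 0
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (N_SHIFTS,):
            raise LengthError(f"feature vector must have {N_SHIFTS} elements")

    @property
    def peak_shift_ms(self) -> float:
        """Shift at which the correlation peaks."""
        return float(SHIFTS_MS[int(np.argmax(self.r))])


def ppmcc(p: np.ndarray, q: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    If either vector is constant the correlation is 0/0; the convention here
    returns 0 (no linear association).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise LengthError(f"length mismatch: {p.shape} vs {q.shape}")
    if p.size < 2:
        raise LengthError("ppmcc needs at least 2 samples")
    dp = p - p.mean()
    dq = q - q.mean()
    denom = np.sqrt(np.dot(dp, dp) * np.dot(dq, dq))
    if denom == 0.0:
        return 0.0
    # clip rounding excursions outside [-1, 1]
    return float(np.clip(np.dot(dp, dq) / denom, -1.0, 1.0))


def timeshift_features(epoch: Epoch, template: TemplateP300) -> FeatureVector:
    """Correlate 31 shifted, renormalized context slices with the template."""
    if epoch.context is None:
        raise InvalidParameterError("epoch is missing its raw context")
    context = np.asarray(epoch.context, dtype=float)
    q = template.samples
    r = np.empty(N_SHIFTS)
    for i in range(N_SHIFTS):
        window = normalize01(context[i : i + EPOCH_SAMPLES])
        r[i] = ppmcc(window, q)
    return FeatureVector(r=r, interval_index=epoch.interval_index, trial_index=epoch.trial_index)


def features_for_trial(epochs: list[Epoch], template: TemplateP300) -> list[FeatureVector]:
    """Feature vectors for all four intervals of one trial."""
    return [timeshift_features(ep, template) for ep in epochs]
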