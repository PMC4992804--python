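"""Filtering, channel averaging, and stimulus-locked epoch extraction.

The analysis signal is the arithmetic mean of the Cz, Pz and Oz channels.
Each trial yields four 280 ms epochs (70 samples at 250 Hz), one per
stimulus interval, each stored together with a 100-sample raw context
(+/- 60 ms) so the time-shift correlation can slide a 70-sample window over
real signal instead of zero padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import paradigm
from .errors import ChannelError, InvalidParameterError, LengthError
from .io import DEFAULT_CHANNELS, EEGRecording

#: samples per epoch at 250 Hz (280 ms)
EPOCH_SAMPLES = 70
#: context margin on each side, samples (60 ms at 250 Hz)
CONTEXT_MARGIN = 15
#: samples per context window
CONTEXT_SAMPLES = EPOCH_SAMPLES + 2 * CONTEXT_MARGIN


@dataclass
class Epoch:
    """One stimulus interval's normalized window plus its raw context.

    ``samples`` are the 70 min-max normalized values (the P vector of the
    correlation); ``context`` is the raw 100-sample window extending 60 ms
    beyond the epoch on each side, kept unnormalized so shifted slices can be
    renormalized independently.
    """

    samples: np.ndarray
    context: np.ndarray
    trial_index: int = 0
    interval_index: int = 0
    start_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.context = np.asarray(self.context, dtype=float)
        if self.samples.shape != (EPOCH_SAMPLES,):
            raise LengthError(f"epoch must have {EPOCH_SAMPLES} samples")
        if self.context.shape != (CONTEXT_SAMPLES,):
            raise LengthError(f"context must have {CONTEXT_SAMPLES} samples")


def normalize01(samples: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant input maps to all 0.5."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise LengthError("normalize01 needs at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def average_channels(
    recording: EEGRecording, labels: tuple[str, ...] = DEFAULT_CHANNELS
) -> np.ndarray:
    """Pointwise mean of the named channels (case-insensitive labels)."""
    if not labels:
        raise ChannelError("at least one channel label required")
    columns = [recording.channel(label) for label in labels]
    return np.mean(columns, axis=0)


def bandpass_notch(
    recording: EEGRecording,
    low: float = 8.0,
    high: float = 30.0,
    notch: float | None = 60.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase band-pass plus optional mains notch, per channel.

    Forward-backward filtering is used so the filter adds no group delay:
    the P300 latency is the very quantity downstream stages measure.
    """
    fs = recording.sampling_rate
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise InvalidParameterError(f"need 0 < low < high < {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if recording.n_samples <= padlen:
        raise LengthError(
            f"signal of {recording.n_samples} samples too short for filter warm-up ({padlen})"
        )
    data = sps.sosfiltfilt(sos, recording.data, axis=0)
    if notch is not None and notch < nyq:
        bn, an = sps.iirnotch(notch, notch_q, fs=fs)
        data = sps.filtfilt(bn, an, data, axis=0)
    return EEGRecording(
        np.ascontiguousarray(data),
        fs,
        recording.channel_labels,
        start_time=recording.start_time,
    )


def extract_epochs(
    signal: np.ndarray,
    trial_onset_ms: float,
    sampling_rate: float = paradigm.DEFAULT_FS,
    trial_index: int = 0,
    grid_snap: str = "up",
) -> list[Epoch]:
    """Cut the four per-stimulus epochs of one trial from a 1-D signal.

    Interval k starts at the first sample-grid multiple at or after
    ``200 k + 81`` ms from trial onset (84/284/484/684 ms at 250 Hz) and runs
    70 samples; the raw context extends 15 samples on each side.  Sample
    windows are half-open ``[start, end)``, 0-based.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("extract_epochs expects a single-channel signal")
    onset_sample = int(round(trial_onset_ms * sampling_rate / 1000.0))
    epochs = []
    for k in range(paradigm.N_STIMULI):
        offset_ms = paradigm.epoch_start_offset_ms(k, sampling_rate, grid_snap)
        start = onset_sample + int(round(offset_ms * sampling_rate / 1000.0))
        c0, c1 = start - CONTEXT_MARGIN, start + EPOCH_SAMPLES + CONTEXT_MARGIN
        if c0 < 0 or c1 > x.size:
            raise LengthError(
                f"signal too short for trial at {trial_onset_ms} ms "
                f"(needs samples [{c0}, {c1}) of {x.size})"
            )
        context = x[c0:c1].copy()
        epochs.append(
            Epoch(
                samples=normalize01(context[CONTEXT_MARGIN : CONTEXT_MARGIN + EPOCH_SAMPLES]),
                context=context,
                trial_index=trial_index,
                interval_index=k,
                start_offset_ms=offset_ms,
            )
        )
    return epochs


def epoch_from_context(
    context: np.ndarray, trial_index: int = 0, interval_index: int = 0,
    start_offset_ms: float = 0.0,
) -> Epoch:
    """Build an Epoch from a raw 100-sample context window (e.g. an average)."""
    context = np.asarray(context, dtype=float)
    return Epoch(
        samples=normalize01(context[CONTEXT_MARGIN : CONTEXT_MARGIN + EPOCH_SAMPLES]),
        context=context,
        trial_index=trial_index,
        interval_index=interval_index,
        start_offset_ms=start_offset_ms,
    )
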