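"""Stimulus paradigm timing.

A trial presents four LED stimuli right-to-left.  Each flash lasts 100 ms and
is followed by a 100 ms inter-stimulus interval; a 250 ms pause separates
trials, so one trial spans 4 x (100 + 100) + 250 = 1050 ms.  The P300 window
for stimulus k nominally runs from ``t + 200k + 81`` ms to ``t + 200k + 360``
ms after trial onset ``t``; at 250 Hz the start is snapped up to the 4 ms
sample grid (84, 284, 484, 684 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

#: default sampling rate, Hz
DEFAULT_FS = 250.0
#: number of stimuli per trial
N_STIMULI = 4
#: flash duration, ms
FLASH_MS = 100.0
#: inter-stimulus interval, ms
ISI_MS = 100.0
#: inter-trial interval, ms
ITI_MS = 250.0
#: epoch window length, ms (70 samples at 250 Hz)
EPOCH_MS = 280.0
#: nominal window start relative to flash onset, ms
EPOCH_OFFSET_MS = 81.0
#: half-width of the time-shift search, ms
SHIFT_MARGIN_MS = 60.0
#: time-shift step, ms (one sample at 250 Hz)
SHIFT_STEP_MS = 4.0
#: number of time-shift correlation features: 2 * 60/4 + 1
N_SHIFTS = 31

#: movement command associated with each stimulus ordinal (right to left)
COMMANDS = ("forward", "right-turn", "left-turn", "backward")


def trial_duration_ms(
    n_stimuli: int = N_STIMULI,
    flash_ms: float = FLASH_MS,
    isi_ms: float = ISI_MS,
    iti_ms: float = ITI_MS,
) -> float:
    """Total duration of one trial (1050 ms in the reference configuration)."""
    return n_stimuli * (flash_ms + isi_ms) + iti_ms


def flash_onset_ms(interval_index: int, flash_ms: float = FLASH_MS, isi_ms: float = ISI_MS) -> float:
    """Onset of the k-th flash relative to trial onset (200 k ms by default)."""
    return (flash_ms + isi_ms) * interval_index


def epoch_start_offset_ms(
    interval_index: int,
    sampling_rate: float = DEFAULT_FS,
    grid_snap: str = "up",
) -> float:
    """Start of the k-th P300 window relative to trial onset, on the sample grid.

    The nominal start is ``200 k + 81`` ms, which does not fall on the 4 ms
    grid of a 250 Hz recording; ``grid_snap='up'`` rounds up to 84/284/484/684
    ms, ``'nearest'`` rounds to the closest grid point.
    """
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be positive")
    nominal = flash_onset_ms(interval_index) + EPOCH_OFFSET_MS
    step = 1000.0 / sampling_rate
    if grid_snap == "up":
        return math.ceil(nominal / step - 1e-9) * step
    if grid_snap == "nearest":
        return round(nominal / step) * step
    raise InvalidParameterError(f"unknown grid_snap {grid_snap!r}")


@dataclass(frozen=True)
class StimulusSchedule:
    """Flash timing of a session: one onset per trial plus paradigm constants."""

    trial_onsets: tuple[float, ...]
    flash_duration: float = FLASH_MS
    inter_stimulus_interval: float = ISI_MS
    inter_trial_interval: float = ITI_MS
    n_stimuli: int = N_STIMULI

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.trial_onsets)
        object.__setattr__(self, "trial_onsets", onsets)
        if self.n_stimuli < 1:
            raise InvalidParameterError("n_stimuli must be >= 1")
        span = self.trial_length_ms
        for a, b in zip(onsets, onsets[1:]):
            if b <= a:
                raise InvalidParameterError("trial onsets must be strictly increasing")
            if b - a < span - 1e-9:
                raise InvalidParameterError(
                    f"trial onsets must be spaced >= trial length ({span} ms)"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)

    @property
    def trial_length_ms(self) -> float:
        return trial_duration_ms(
            self.n_stimuli,
            self.flash_duration,
            self.inter_stimulus_interval,
            self.inter_trial_interval,
        )

    def flash_onsets_ms(self, trial_index: int) -> list[float]:
        """Flash onsets of one trial, in ms from recording start."""
        t = self.trial_onsets[trial_index]
        step = self.flash_duration + self.inter_stimulus_interval
        return [t + step * k for k in range(self.n_stimuli)]


def regular_schedule(n_trials: int, start_ms: float = 0.0) -> StimulusSchedule:
    """Back-to-back trials at the default 1050 ms pitch."""
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    pitch = trial_duration_ms()
    return StimulusSchedule(tuple(start_ms + i * pitch for i in range(n_trials)))
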