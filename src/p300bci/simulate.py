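"""Synthetic labeled EEG sessions for the oddball paradigm.

Each simulated trial plays the four-flash sequence and adds a positive
P300-like deflection — a Gaussian bump peaking ~300 ms after the attended
stimulus's flash — on top of band-limited Gaussian background noise on all
channels.  Per-trial latency jitter, multiplicative amplitude variability
and an optional linear fatigue drift emulate the trial-to-trial variability
the decision modes have to absorb.  All randomness flows from a single seed
through one generator with per-trial draws in a fixed order, so identical
configs give bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from . import paradigm
from .errors import InvalidParameterError
from .io import DEFAULT_CHANNELS, EEGRecording

#: width (Gaussian sigma, ms) of the synthetic P300 bump used in sessions
DEFAULT_P300_SIGMA_MS = 40.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic session.

    Amplitudes are in microvolts: the P300 deflection defaults to 15 uV
    (the reported 10-25 uV range) with +/-20% uniform per-trial variability,
    peaking 300 ms post-stimulus with uniform latency jitter of +/-20 ms by
    default (bounded by the +/-60 ms shift search).  ``noise_sd`` is the
    standard deviation of the band-limited background noise per channel.
    ``fatigue_rate`` r shrinks the amplitude by a factor (1 - r * trial) and
    widens the jitter half-width by (1 + r * trial), clipped at 60 ms.
    """

    target_sequence: tuple[int, ...]
    sampling_rate: float = paradigm.DEFAULT_FS
    n_channels: int = 3
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    p300_amplitude: float = 15.0
    amplitude_variability: float = 0.2
    p300_peak_latency: float = 300.0
    p300_sigma: float = DEFAULT_P300_SIGMA_MS
    latency_jitter: float = 20.0
    noise_sd: float = 10.0
    noise_band: tuple[float, float] = (1.0, 30.0)
    fatigue_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_sequence", tuple(int(k) for k in self.target_sequence))
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if self.n_trials < 1:
            raise InvalidParameterError("need at least one trial")
        if any(k < 0 or k >= paradigm.N_STIMULI for k in self.target_sequence):
            raise InvalidParameterError(
                f"target indices must be in 0..{paradigm.N_STIMULI - 1}"
            )
        if self.latency_jitter < 0:
            raise InvalidParameterError("latency_jitter must be >= 0")
        if self.p300_amplitude < 0:
            raise InvalidParameterError("p300_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_channels != len(self.channel_labels):
            raise InvalidParameterError("one label per channel required")

    @property
    def n_trials(self) -> int:
        return len(self.target_sequence)


@dataclass
class LabeledSession:
    """A simulated recording plus everything a test needs to grade it."""

    recording: EEGRecording
    schedule: paradigm.StimulusSchedule
    truth: list[int]
    injected_latencies: list[float]
    config: SimulationConfig

    def __post_init__(self) -> None:
        if len(self.truth) != self.schedule.n_trials:
            raise InvalidParameterError("truth length must match the schedule")


def p300_waveform(
    peak_latency: float,
    amplitude: float,
    duration: float = 400.0,
    sampling_rate: float = paradigm.DEFAULT_FS,
    sigma: float | None = None,
) -> np.ndarray:
    """A smooth unimodal positive deflection sampled over [0, duration).

    The bump is Gaussian, peaks at ``peak_latency`` ms with maximum value
    ``amplitude``, and decays below 1% of the amplitude at the window edges.
    If ``sigma`` (ms) is not given it is derived from the distance between
    the peak and the nearest edge so the edge condition holds by
    construction.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if not 0 <= peak_latency <= duration:
        raise InvalidParameterError("peak_latency must lie within [0, duration]")
    step = 1000.0 / sampling_rate
    t = np.arange(0.0, duration - step / 2, step)
    if sigma is None:
        edge = min(peak_latency, duration - peak_latency)
        # exp(-0.5 (edge/sigma)^2) < 0.01 needs sigma < edge / 3.035; the
        # divisor 3.5 keeps even the sample just inside the edge below 1%
        sigma = max(edge, step) / 3.5
    return amplitude * np.exp(-0.5 * ((t - peak_latency) / sigma) ** 2)


def _band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    n_channels: int,
    sd: float,
    band: tuple[float, float],
    fs: float,
) -> np.ndarray:
    """White Gaussian noise filtered to the analysis band, rescaled to sd."""
    white = rng.standard_normal((n_samples, n_channels))
    if sd == 0:
        return np.zeros((n_samples, n_channels))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white, axis=0)
    scale = shaped.std(axis=0)
    scale[scale == 0] = 1.0
    return shaped / scale * sd


def simulate_session(config: SimulationConfig) -> LabeledSession:
    """Generate one labeled session under the paradigm timing.

    For each trial the P300 bump is added at the attended stimulus's
    interval only — peak at flash onset + 300 ms + jitter — identically on
    all channels, on top of independent band-limited noise per channel.
    Draws per trial happen in a fixed order (jitter, then amplitude factor)
    from a single seeded generator.
    """
    fs = config.sampling_rate
    schedule = paradigm.regular_schedule(config.n_trials)
    duration_ms = schedule.trial_onsets[-1] + schedule.trial_length_ms + 100.0
    n_samples = int(round(duration_ms * fs / 1000.0))
    rng = np.random.default_rng(config.seed)

    data = _band_limited_noise(
        rng, n_samples, config.n_channels, config.noise_sd, config.noise_band, fs
    )
    t_ms = np.arange(n_samples) * 1000.0 / fs

    jitters: list[float] = []
    for i, target in enumerate(config.target_sequence):
        half = min(
            paradigm.SHIFT_MARGIN_MS,
            config.latency_jitter * (1.0 + config.fatigue_rate * i),
        )
        jitter = float(rng.uniform(-half, half)) if half > 0 else 0.0
        amp_factor = float(
            rng.uniform(1.0 - config.amplitude_variability, 1.0 + config.amplitude_variability)
        )
        amp_factor *= max(0.0, 1.0 - config.fatigue_rate * i)
        jitters.append(jitter)

        peak_ms = (
            schedule.trial_onsets[i]
            + paradigm.flash_onset_ms(target)
            + config.p300_peak_latency
            + jitter
        )
        lo = max(0, int((peak_ms - 5 * config.p300_sigma) * fs / 1000.0))
        hi = min(n_samples, int((peak_ms + 5 * config.p300_sigma) * fs / 1000.0) + 1)
        bump = config.p300_amplitude * amp_factor * np.exp(
            -0.5 * ((t_ms[lo:hi] - peak_ms) / config.p300_sigma) ** 2
        )
        data[lo:hi] += bump[:, None]

    recording = EEGRecording(data, fs, config.channel_labels)
    return LabeledSession(
        recording=recording,
        schedule=schedule,
        truth=list(config.target_sequence),
        injected_latencies=jitters,
        config=config,
    )


def blocked_targets(
    n_trials: int, block_length: int = 5, seed: int | None = None
) -> tuple[int, ...]:
    """Random target sequence in constant blocks.

    Emulates an operator attending one command for several consecutive
    trials (as the sequential decision modes assume) before switching to a
    new, different random target.
    """
    if n_trials < 1 or block_length < 1:
        raise InvalidParameterError("n_trials and block_length must be >= 1")
    rng = np.random.default_rng(seed)
    targets: list[int] = []
    current = int(rng.integers(paradigm.N_STIMULI))
    while len(targets) < n_trials:
        targets.extend([current] * block_length)
        nxt = int(rng.integers(paradigm.N_STIMULI - 1))
        current = nxt if nxt < current else nxt + 1
    return tuple(targets[:n_trials])
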