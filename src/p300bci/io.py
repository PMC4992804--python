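"""Reading and writing recordings, event schedules, models and configs.

Recordings travel as EDF (European Data Format, 16-bit) or as delimited text
with a ``time_ms`` column followed by one column per channel.  Events and
ground-truth sequences are tab-separated text.  Trained models (network
weights plus the subject's P300 template) are JSON so tests can pin exact
values.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import paradigm
from .errors import ChannelError, FormatError, InvalidParameterError, ModelFormatError

DEFAULT_CHANNELS = ("Cz", "Pz", "Oz")


@dataclass
class EEGRecording:
    """Sampled multichannel EEG, in microvolts.

    ``data`` is samples x channels; ``channel_labels`` name the columns
    (``Cz``, ``Pz``, ``Oz`` in the reference montage); ``start_time`` is the
    ms offset of the first sample.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be samples x channels")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise InvalidParameterError("one label per channel required")
        lowered = [c.lower() for c in self.channel_labels]
        if len(set(lowered)) != len(lowered):
            raise InvalidParameterError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label (case-insensitive)."""
        lowered = [c.lower() for c in self.channel_labels]
        try:
            idx = lowered.index(label.lower())
        except ValueError:
            raise ChannelError(f"channel {label!r} not in {self.channel_labels}") from None
        return self.data[:, idx]


# ---------------------------------------------------------------------------
# delimited-text recordings

def write_recording_csv(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as CSV: header row, then time_ms plus one column per channel."""
    t = recording.start_time + np.arange(recording.n_samples) * 1000.0 / recording.sampling_rate
    frame = pd.DataFrame({"time_ms": t})
    for i, label in enumerate(recording.channel_labels):
        frame[label] = recording.data[:, i]
    frame.to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(path: str | Path) -> EEGRecording:
    frame = pd.read_csv(path, float_precision="round_trip")
    if "time_ms" not in frame.columns:
        raise FormatError(f"{path}: missing time_ms column")
    labels = [c for c in frame.columns if c != "time_ms"]
    if not labels:
        raise FormatError(f"{path}: no channel columns")
    t = frame["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * max(1.0, abs(dt[0]))):
        raise FormatError(f"{path}: non-uniform sampling")
    fs = 1000.0 / dt[0]
    data = frame[labels].to_numpy(dtype=float)
    return EEGRecording(data, fs, tuple(labels), start_time=float(t[0]))


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value, width: int) -> bytes:
    if isinstance(value, float):
        # densest decimal representation that fits the fixed-width field
        for precision in range(14, 0, -1):
            text = f"{value:.{precision}g}"
            if len(text) <= width:
                break
    else:
        text = f"{value}"
    if len(text) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return text.ljust(width).encode("ascii")


def write_recording_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write a 16-bit EDF file with a single data record spanning the recording.

    Physical dimension is microvolts; each channel is scaled to the full
    digital range, so the round-trip quantization error is below
    (max - min) / 65535 per channel.
    """
    data = recording.data
    n_samples, n_ch = data.shape
    phys_min = data.min(axis=0)
    phys_max = data.max(axis=0)
    # avoid a zero physical span for constant channels
    span = phys_max - phys_min
    phys_max = np.where(span <= 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("synthetic subject", 80),
            _edf_field("p300bci recording", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(1, 8),
            _edf_field(float(n_samples / recording.sampling_rate), 8),
            _edf_field(n_ch, 4),
        ]
    )
    per_signal = []
    for spec_width, values in [
        (16, recording.channel_labels),
        (80, ["" for _ in range(n_ch)]),
        (8, ["uV" for _ in range(n_ch)]),
        (8, [float(v) for v in phys_min]),
        (8, [float(v) for v in phys_max]),
        (8, [dig_min] * n_ch),
        (8, [dig_max] * n_ch),
        (80, ["" for _ in range(n_ch)]),
        (8, [n_samples] * n_ch),
        (32, ["" for _ in range(n_ch)]),
    ]:
        per_signal.append(b"".join(_edf_field(v, spec_width) for v in values))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(per_signal))
        for i in range(n_ch):
            scale = (dig_max - dig_min) / (phys_max[i] - phys_min[i])
            digital = np.round((data[:, i] - phys_min[i]) * scale + dig_min)
            fh.write(digital.astype("<i2").tobytes())


def read_recording_edf(
    path: str | Path, required_channels: tuple[str, ...] | None = None
) -> EEGRecording:
    """Read an EDF recording via MNE; channel labels match case-insensitively."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise FormatError("EDF support requires the 'mne' package") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # MNE returns volts for EEG channels
    rec = EEGRecording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))
    if required_channels:
        for label in required_channels:
            rec.channel(label)  # raises ChannelError if absent
    return rec


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording, dispatching on ``format`` or the file suffix."""
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "csv")
    if fmt == "edf":
        return read_recording_edf(path)
    if fmt == "csv":
        return read_recording_csv(path)
    raise InvalidParameterError(f"unknown recording format {fmt!r}")


def write_recording(recording: EEGRecording, path: str | Path, format: str | None = None) -> None:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "csv")
    if fmt == "edf":
        write_recording_edf(recording, path)
    elif fmt == "csv":
        write_recording_csv(recording, path)
    else:
        raise InvalidParameterError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# events and truth

def write_events_tsv(
    schedule: paradigm.StimulusSchedule, truth: list[int] | None, path: str | Path
) -> None:
    """One row per flash: onset_ms, stimulus_index, is_target."""
    rows = []
    for i in range(schedule.n_trials):
        for k, onset in enumerate(schedule.flash_onsets_ms(i)):
            is_target = int(truth is not None and truth[i] == k)
            rows.append((onset, k, is_target))
    pd.DataFrame(rows, columns=["onset_ms", "stimulus_index", "is_target"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_events(path: str | Path) -> tuple[paradigm.StimulusSchedule, pd.DataFrame]:
    """Read a flash-event table and reconstruct the trial schedule.

    Returns the schedule plus the raw per-flash table (onset_ms,
    stimulus_index and, when present, is_target).
    """
    frame = pd.read_csv(path, sep="\t")
    if frame.empty:
        warnings.warn(f"{path}: empty event file", stacklevel=2)
        return paradigm.StimulusSchedule(()), frame
    for col in ("onset_ms", "stimulus_index"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col}")
    onsets = frame["onset_ms"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise FormatError(f"{path}: onsets must be strictly increasing")
    stim = frame["stimulus_index"].to_numpy()
    if stim.min() < 0 or stim.max() >= paradigm.N_STIMULI:
        raise FormatError(
            f"{path}: stimulus_index outside 0..{paradigm.N_STIMULI - 1}"
        )
    trial_onsets = onsets[stim == 0]
    if len(trial_onsets) == 0:
        raise FormatError(f"{path}: no stimulus-0 flashes; cannot infer trial onsets")
    return paradigm.StimulusSchedule(tuple(trial_onsets)), frame


def write_truth_tsv(truth: list[int], path: str | Path) -> None:
    pd.DataFrame({"trial": range(len(truth)), "target_index": truth}).to_csv(
        path, sep="\t", index=False
    )


def read_truth_tsv(path: str | Path) -> list[int]:
    frame = pd.read_csv(path, sep="\t")
    if "target_index" not in frame.columns:
        raise FormatError(f"{path}: missing target_index column")
    truth = [int(v) for v in frame["target_index"]]
    if any(v < 0 or v >= paradigm.N_STIMULI for v in truth):
        raise FormatError(f"{path}: target_index outside 0..{paradigm.N_STIMULI - 1}")
    return truth


# ---------------------------------------------------------------------------
# model files

def save_model(model, path: str | Path) -> None:
    """Write a trained network (and its template) as JSON at full precision."""
    payload = {
        "n": model.n,
        "m": model.m,
        "w": model.w.tolist(),
        "b": model.b.tolist(),
        "hw": model.hw.tolist(),
        "ob": float(model.ob),
        "threshold": float(model.threshold),
    }
    if model.template is not None:
        payload["template"] = {
            "samples": model.template.samples.tolist(),
            "n_source_epochs": model.template.n_source_epochs,
            "subject_id": model.template.subject_id,
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path):
    from .network import NetworkModel
    from .template import TemplateP300

    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelFormatError(f"{path}: cannot parse model file: {exc}") from exc
    try:
        n, m = int(payload["n"]), int(payload["m"])
        w = np.asarray(payload["w"], dtype=float)
        b = np.asarray(payload["b"], dtype=float)
        hw = np.asarray(payload["hw"], dtype=float)
        ob = float(payload["ob"])
        threshold = float(payload["threshold"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: missing or malformed field: {exc}") from exc
    if w.shape != (m, n) or b.shape != (m,) or hw.shape != (m,):
        raise ModelFormatError(
            f"{path}: weight shapes {w.shape}/{b.shape}/{hw.shape} do not match n={n}, m={m}"
        )
    template = None
    if "template" in payload:
        tpl = payload["template"]
        template = TemplateP300(
            samples=np.asarray(tpl["samples"], dtype=float),
            n_source_epochs=int(tpl.get("n_source_epochs", 0)),
            subject_id=str(tpl.get("subject_id", "")),
        )
    return NetworkModel(w=w, b=b, hw=hw, ob=ob, threshold=threshold, template=template)


# ---------------------------------------------------------------------------
# configs

def load_config(path: str | Path) -> dict:
    """Load a YAML config; returns an empty dict for an empty file."""
    text = Path(path).read_text()
    loaded = yaml.safe_load(text)
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return loaded
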