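"""Session-level evaluation: accuracy, information transfer rate, fatigue
accumulation, and trajectory comparison.

ITR follows the Wolpaw convention: bits per selection
``log2 Ks + Pa log2 Pa + (1 - Pa) log2((1 - Pa)/(Ks - 1))`` scaled by 60 /
CTI where CTI = T_exp / N_o is the mean time per correct command.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .features import ppmcc
from .paradigm import N_STIMULI


def bits_per_command(p_a: float, k_s: int = N_STIMULI) -> float:
    """Wolpaw bits per selection for accuracy ``p_a`` over ``k_s`` choices."""
    if not 0.0 <= p_a <= 1.0:
        raise InvalidParameterError("P_a must be in [0, 1]")
    if k_s < 2:
        raise InvalidParameterError("K_s must be >= 2")
    bits = math.log2(k_s)
    if p_a > 0.0:
        bits += p_a * math.log2(p_a)
    if p_a < 1.0:
        bits += (1.0 - p_a) * math.log2((1.0 - p_a) / (k_s - 1))
    return bits


def itr(t_exp: float, n_o: int, p_a: float, k_s: int = N_STIMULI) -> float:
    """Information transfer rate in bits/min.

    ``t_exp`` is the experimental time in seconds and ``n_o`` the number of
    correct command events, so CTI = t_exp / n_o seconds per command.  With
    no correct commands the rate is 0.
    """
    if t_exp <= 0:
        raise InvalidParameterError("T_exp must be positive")
    if n_o < 0:
        raise InvalidParameterError("N_o must be >= 0")
    if n_o == 0:
        return 0.0
    cti = t_exp / n_o
    return bits_per_command(p_a, k_s) * 60.0 / cti


@dataclass
class SessionMetrics:
    """Per-session tallies and the derived accuracy/ITR figures."""

    n_trials: int
    correct: int
    wrong: int
    non_recognition: int
    t_exp: float                 # experimental time, s
    k_s: int = N_STIMULI

    def __post_init__(self) -> None:
        if self.correct + self.wrong + self.non_recognition != self.n_trials:
            raise InvalidParameterError(
                "correct + wrong + non_recognition must equal n_trials"
            )

    @property
    def correct_rate(self) -> float:
        """Fraction of trials credited to a correct command."""
        return self.correct / self.n_trials

    @property
    def wrong_rate(self) -> float:
        return self.wrong / self.n_trials

    @property
    def non_recognition_rate(self) -> float:
        return self.non_recognition / self.n_trials

    @property
    def rates_percent(self) -> tuple[float, float, float]:
        return (
            100.0 * self.correct_rate,
            100.0 * self.wrong_rate,
            100.0 * self.non_recognition_rate,
        )


@dataclass
class ModeMetrics(SessionMetrics):
    """SessionMetrics plus command-level accuracy and ITR for one mode."""

    n_correct_commands: int = 0
    n_wrong_commands: int = 0

    @property
    def n_commands(self) -> int:
        return self.n_correct_commands + self.n_wrong_commands

    @property
    def p_a(self) -> float:
        """Command accuracy: correct commands over emitted commands."""
        if self.n_commands == 0:
            return float("nan")
        return self.n_correct_commands / self.n_commands

    @property
    def itr_bits_per_min(self) -> float:
        if self.n_commands == 0 or self.n_correct_commands == 0:
            return 0.0
        return itr(self.t_exp, self.n_correct_commands, self.p_a, self.k_s)


@dataclass
class FatigueCurve:
    """Cumulative wrong-recognition profile of a session."""

    en: np.ndarray               # cumulative wrong count per trial
    et: int                      # total wrong count
    er: np.ndarray               # accumulation rate per trial
    defined: bool                # False when Et == 0


def fatigue_curve(wrong_flags, printed_form: bool = False) -> FatigueCurve:
    """Accumulation rate of wrong recognitions across a session.

    ``er[i] = en[i] / et`` by default, a non-decreasing curve reaching 1 at
    the final trial — late-session fatigue shows up as a late, steep rise.
    ``printed_form=True`` instead computes ``(en - et)/et``, the same curve
    shifted to [-1, 0].  A session with no wrong recognitions has no defined
    rate and is flagged.
    """
    flags = np.asarray(wrong_flags, dtype=bool)
    if flags.size < 1:
        raise InvalidParameterError("need at least one trial")
    en = np.cumsum(flags.astype(int))
    et = int(en[-1])
    if et == 0:
        return FatigueCurve(en=en, et=0, er=np.full(flags.size, np.nan), defined=False)
    er = (en - et) / et if printed_form else en / et
    return FatigueCurve(en=en, et=et, er=er.astype(float), defined=True)


# ---------------------------------------------------------------------------
# trajectory comparison


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _resample_by_arc_length(points: np.ndarray, n: int) -> np.ndarray:
    s = _arc_lengths(points)
    total = s[-1]
    grid = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(grid, s, points[:, 0]), np.interp(grid, s, points[:, 1])]
    )


def _lateral_deviation(points: np.ndarray, chord_start, chord_dir) -> np.ndarray:
    rel = points - chord_start
    # signed perpendicular distance from the chord line
    return rel[:, 0] * (-chord_dir[1]) + rel[:, 1] * chord_dir[0]


def compare_trajectories(
    actual: np.ndarray, desired: np.ndarray, n_resample: int = 200
) -> tuple[float, float]:
    """Similarity of a walked trajectory to the desired one.

    Both paths are resampled to ``n_resample`` points uniform in normalized
    arc length; the correlation is computed between their lateral-deviation
    profiles relative to the desired path's start-to-end chord.  Returns
    ``(ppmcc, length_difference_percent)`` where the length difference is
    ``(len(actual) - len(desired)) / len(desired) * 100``.  Two paths with
    identical (possibly constant) deviation profiles correlate at 1.
    """
    actual = np.asarray(actual, dtype=float)
    desired = np.asarray(desired, dtype=float)
    for name, pts in (("actual", actual), ("desired", desired)):
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidParameterError(f"{name} must be >= 2 points of (x, y)")
        if _arc_lengths(pts)[-1] <= 0:
            raise InvalidParameterError(f"{name} trajectory has zero length")

    len_a = _arc_lengths(actual)[-1]
    len_d = _arc_lengths(desired)[-1]
    length_diff = (len_a - len_d) / len_d * 100.0

    chord = desired[-1] - desired[0]
    norm = np.linalg.norm(chord)
    chord_dir = chord / norm if norm > 0 else np.array([1.0, 0.0])
    dev_a = _lateral_deviation(_resample_by_arc_length(actual, n_resample), desired[0], chord_dir)
    dev_d = _lateral_deviation(_resample_by_arc_length(desired, n_resample), desired[0], chord_dir)

    if np.ptp(dev_a) == 0 and np.ptp(dev_d) == 0:
        # both profiles constant (straight paths along the chord): identical shapes
        r = 1.0 if np.allclose(dev_a, dev_d, atol=1e-9 * max(1.0, len_d)) else 0.0
    else:
        r = ppmcc(dev_a, dev_d)
    return float(r), float(length_diff)
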