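"""Threshold alert engine.

A sample is flagged when heart rate exceeds the configured threshold
(optionally also requiring speed above its threshold).  The default HR
threshold is 150 BPM; when an athlete age is supplied the threshold follows
the conventional age-predicted maximum heart rate, 220 − age.

A triggered alert takes 2 s to reset, which has two consequences here: a
new flagged run starting less than the refractory period after the previous
one merges into the same *episode*, and the actuator stays on for at least
that long.  The per-sample flag itself remains instantaneous — consecutive
above-threshold samples each carry flag 1, as in the device logs.

The vibration motor is abstracted behind :func:`actuate`, a pure function of
the episode-active state transition; driving hardware is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .session_io import PhaseSession

__all__ = [
    "AlertLogic",
    "AlertConfig",
    "AlertEpisode",
    "ActuatorCommand",
    "max_heart_rate",
    "flag_series",
    "episodes",
    "actuate",
]


def max_heart_rate(age_years: int) -> float:
    """Age-predicted maximum heart rate, 220 − age (BPM)."""
    if not 0 < age_years <= 120:
        raise ValueError(f"age_years must be in (0, 120], got {age_years}")
    return 220.0 - age_years


class AlertLogic(str, Enum):
    #: flag on heart rate alone (default; matches the device logs)
    HR_ONLY = "hr_only"
    #: flag only when both heart rate and speed exceed their thresholds
    HR_AND_SPEED = "hr_and_speed"


@dataclass(frozen=True)
class AlertConfig:
    """Thresholds and reset behaviour of the alert engine.

    If ``age_years`` is given, ``hr_threshold_bpm`` is derived as 220 − age
    and must not be set independently.
    """

    hr_threshold_bpm: float = 150.0
    speed_threshold_cm_s: float = 100.0
    refractory_s: float = 2.0
    age_years: int | None = None
    logic: AlertLogic = AlertLogic.HR_ONLY

    def __post_init__(self) -> None:
        if self.age_years is not None:
            derived = max_heart_rate(self.age_years)
            if self.hr_threshold_bpm not in (150.0, derived):
                raise ValueError(
                    "hr_threshold_bpm conflicts with age_years "
                    f"({self.hr_threshold_bpm} != 220 - {self.age_years})"
                )
            object.__setattr__(self, "hr_threshold_bpm", derived)
        if not self.hr_threshold_bpm > 0 or not self.speed_threshold_cm_s > 0:
            raise ValueError("thresholds must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


@dataclass(frozen=True)
class AlertEpisode:
    """A maximal run of flagged samples (1-based sample ordinals, inclusive)."""

    start_index: int
    end_index: int
    peak_hr_bpm: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("episode start after end")
        if self.n_samples != self.end_index - self.start_index + 1:
            raise ValueError("n_samples inconsistent with start/end")


def flag_series(session: PhaseSession, config: AlertConfig) -> np.ndarray:
    """Instantaneous alert flag per sample (0/1 int array).

    ``hr_only``: flag iff hr > hr_threshold.  ``hr_and_speed``: additionally
    require speed > speed_threshold.
    """
    hr = session.channel("hr_bpm")
    flags = hr > config.hr_threshold_bpm
    if config.logic is AlertLogic.HR_AND_SPEED:
        flags &= session.channel("speed_cm_s") > config.speed_threshold_cm_s
    return flags.astype(int)


def episodes(
    flags: Sequence[int],
    sample_period_s: float = 1.0,
    merge_gap_s: float = 2.0,
    hr_bpm: Sequence[float] | None = None,
) -> list[AlertEpisode]:
    """Group flagged samples into alert episodes.

    Consecutive flagged samples form a run; two runs whose separating gap is
    shorter than ``merge_gap_s`` merge into one episode (the refractory
    reset: the alert has not cleared before re-triggering).  A gap of k
    unflagged samples lasts k·sample_period_s.  ``merge_gap_s = 0`` yields
    exactly the maximal runs.  ``hr_bpm``, when given, fills each episode's
    peak heart rate; otherwise the peak is NaN.
    """
    if merge_gap_s < 0:
        raise ValueError("merge_gap_s must be >= 0")
    f = np.asarray(flags, dtype=int)
    if f.ndim != 1:
        raise ValueError("flags must be one-dimensional")
    hr = None if hr_bpm is None else np.asarray(hr_bpm, dtype=float)
    idx = np.flatnonzero(f)  # 0-based positions of flagged samples
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        gap_s = (int(i) - prev - 1) * sample_period_s
        if int(i) == prev + 1 or gap_s < merge_gap_s:
            prev = int(i)
        else:
            runs.append((start, prev))
            start = prev = int(i)
    runs.append((start, prev))
    out = []
    for lo, hi in runs:
        peak = float(np.max(hr[lo : hi + 1])) if hr is not None else math.nan
        out.append(
            AlertEpisode(
                start_index=lo + 1,
                end_index=hi + 1,
                peak_hr_bpm=peak,
                n_samples=hi - lo + 1,
            )
        )
    return out


class ActuatorCommand(str, Enum):
    START = "start"
    STOP = "stop"
    NONE = "none"


def actuate(previous_active: bool, episode_active: bool) -> ActuatorCommand:
    """Vibration-motor command for an episode-active state transition.

    Pure contract boundary for the (out-of-scope) hardware: start on the
    rising edge, stop on the falling edge, no-op otherwise.
    """
    if episode_active and not previous_active:
        return ActuatorCommand.START
    if previous_active and not episode_active:
        return ActuatorCommand.STOP
    return ActuatorCommand.NONE
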