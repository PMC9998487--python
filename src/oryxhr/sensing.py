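"""Simulated ventricular-sense detection of the implanted biologger.

The real device's detection firmware is proprietary; this minimal model
— an upward threshold crossing that starts a refractory "blank" period —
reproduces its documented phenomenology: with a short blank interval the
tall bovid T wave crosses the threshold outside the refractory window
and every heartbeat is counted twice (oversensing), while a 300-ms blank
suppresses the T-wave crossing and recovers the true rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, UndefinedRateError
from .synth import EcgStrip

__all__ = [
    "SenseParams",
    "SenseTrain",
    "EpisodeFlag",
    "TACHYCARDIA_BPM",
    "ASYSTOLE_GAP_S",
    "simulate_sensing",
    "derived_hr",
    "flag_episodes",
]

#: Device episode thresholds (inclusive).
TACHYCARDIA_BPM = 125.0
ASYSTOLE_GAP_S = 4.5


@dataclass(frozen=True)
class SenseParams:
    """Sensing threshold (mV) and blank interval (ms, in [100, 500])."""

    threshold: float = 0.15
    blank: float = 300.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ParameterError("threshold must be > 0")
        if not 100.0 <= self.blank <= 500.0:
            raise ParameterError("blank must be within [100, 500] ms")


@dataclass
class SenseTrain:
    """Ventricular-sense timestamps for one strip."""

    sense_times: np.ndarray  # ms offsets, strictly increasing
    blank_used: float
    strip_ref: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sense_times)


def simulate_sensing(strip: EcgStrip, params: SenseParams = SenseParams()) -> SenseTrain:
    """Emit a sense at each upward threshold crossing outside blanking.

    A crossing is a sample pair with ``v[k-1] < threshold <= v[k]``; the
    crossing is kept when it falls at least ``blank`` ms after the
    previously kept sense.  Deterministic.
    """
    v = np.asarray(strip.samples, dtype=float)
    if v.size == 0:
        raise InputError("empty strip")
    cross = np.flatnonzero((v[:-1] < params.threshold) & (v[1:] >= params.threshold)) + 1
    times = cross / strip.sampling_rate * 1000.0
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= params.blank:
            kept.append(t)
            last = t
    return SenseTrain(sense_times=np.asarray(kept), blank_used=params.blank,
                      strip_ref=strip.strip_id or strip.animal_id)


def derived_hr(train: SenseTrain) -> float:
    """Device heart rate: 60000 / mean successive inter-sense interval (ms)."""
    if len(train) < 2:
        raise UndefinedRateError("need >= 2 senses to derive a rate")
    return 60000.0 / float(np.mean(np.diff(train.sense_times)))


@dataclass(frozen=True)
class EpisodeFlag:
    """A device-defined episode: tachycardia (bpm) or asystole (gap s)."""

    kind: str  # "tachycardia" | "asystole"
    time: object  # timestamp of the record, or ms offset of the gap end
    value: float


def flag_episodes(source: Union[pd.DataFrame, SenseTrain]) -> list:
    """Flag tachycardia (rate >= 125 bpm) and asystole (gap >= 4.5 s).

    Accepts either a 2-min HR record frame (columns ``timestamp`` and
    ``hr_bpm``) — flagging tachycardic records — or a :class:`SenseTrain`
    — flagging long inter-sense gaps.  Boundary values are flagged
    (thresholds are inclusive).
    """
    flags: list = []
    if isinstance(source, SenseTrain):
        if len(source) >= 2:
            gaps = np.diff(source.sense_times) / 1000.0
            for end, gap in zip(source.sense_times[1:], gaps):
                if gap >= ASYSTOLE_GAP_S:
                    flags.append(EpisodeFlag("asystole", float(end), float(gap)))
        return flags
    for _, row in source[source["hr_bpm"] >= TACHYCARDIA_BPM].iterrows():
        flags.append(EpisodeFlag("tachycardia", row["timestamp"], float(row["hr_bpm"])))
    return flags
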