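"""Rule-based channel-current recognition on 1 kHz current streams.

The recognition rule: an excursion qualifies as a channel current when the
current changes by more than ``amp_threshold`` (default 2 pA) relative to its
baseline within ``onset_window`` (default 10 ms) and then returns to the
baseline within ``return_min``..``return_max`` (default 0.01-1 s).  Both
positive and negative excursions qualify (inward currents are negative).

The baseline is a trailing running median of baseline-conforming samples and
is frozen at the onset of a candidate event so that the event cannot
contaminate its own reference.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import InvalidParameterError
from .trace import CurrentTrace

__all__ = [
    "DetectorConfig",
    "ContactConfig",
    "EventKind",
    "DetectionEvent",
    "estimate_baseline",
    "detect_channel_events",
    "detect_contact",
    "detect_rupture",
    "decide_window",
]


@dataclass
class DetectorConfig:
    """Parameters of the channel-current recognition rule."""

    amp_threshold: float = 2.0  # pA
    onset_window: float = 10.0  # ms
    return_min: float = 0.01  # s
    return_max: float = 1.0  # s
    return_tolerance: float = 1.0  # pA
    baseline_window: float = 100.0  # ms
    analysis_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if not (0 < self.return_min < self.return_max):
            raise InvalidParameterError("need 0 < return_min < return_max")
        if self.amp_threshold <= 0 or self.onset_window <= 0:
            raise InvalidParameterError("amp_threshold and onset_window must be > 0")
        if self.return_tolerance <= 0 or self.baseline_window <= 0:
            raise InvalidParameterError("return_tolerance and baseline_window must be > 0")
        if self.analysis_rate <= 0:
            raise InvalidParameterError("analysis_rate must be > 0")

    def to_dict(self) -> dict:
        return {
            "amp_threshold": self.amp_threshold,
            "onset_window": self.onset_window,
            "return_min": self.return_min,
            "return_max": self.return_max,
            "return_tolerance": self.return_tolerance,
            "baseline_window": self.baseline_window,
            "analysis_rate": self.analysis_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        return cls(**d)


@dataclass
class ContactConfig:
    """Thresholds for probe-contact and membrane-rupture recognition."""

    contact_threshold: float = 100.0  # pA
    sustained_threshold: float = 100.0  # pA
    sustained_dur: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.contact_threshold <= 0 or self.sustained_threshold <= 0:
            raise InvalidParameterError("thresholds must be > 0")
        if self.sustained_dur <= 0:
            raise InvalidParameterError("sustained_dur must be > 0")

    def to_dict(self) -> dict:
        return {
            "contact_threshold": self.contact_threshold,
            "sustained_threshold": self.sustained_threshold,
            "sustained_dur": self.sustained_dur,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContactConfig":
        return cls(**d)


class EventKind(str, Enum):
    CHANNEL_EVENT = "channel_event"
    CONTACT_TRANSIENT = "contact_transient"
    BACKGROUND_SPIKE = "background_spike"


@dataclass
class DetectionEvent:
    """One detected transient, with signed amplitude relative to baseline."""

    onset_t: float  # s
    end_t: float  # s
    amplitude: float  # pA
    kind: EventKind

    @property
    def duration(self) -> float:
        return self.end_t - self.onset_t


def estimate_baseline(samples: np.ndarray, window: float, rate: float) -> np.ndarray:
    """Trailing running median of the last ``window`` ms at the given rate.

    For the first samples (shorter history than the window) the median of the
    available prefix is used; if the window exceeds the trace a single global
    median is returned for every sample.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if n == 0:
        return np.zeros(0)
    w = int(round(window / 1000.0 * rate))
    if w < 3:
        raise InvalidParameterError("baseline window must span at least 3 samples")
    if w >= n:
        return np.full(n, np.median(samples))
    out = np.empty(n)
    for i in range(min(w - 1, n)):
        out[i] = np.median(samples[: i + 1])
    if n >= w:
        from numpy.lib.stride_tricks import sliding_window_view

        out[w - 1:] = np.median(sliding_window_view(samples, w), axis=1)
    return out


def detect_channel_events(trace: CurrentTrace, cfg: Optional[DetectorConfig] = None) -> list[DetectionEvent]:
    """Apply the recognition rule to a trace at the analysis rate.

    Traces at an integer multiple of ``cfg.analysis_rate`` are decimated by
    block averaging first.  Returns non-overlapping events in onset order;
    excursions that return too quickly are classified as background spikes,
    excursions that fail to return within ``return_max`` are reported as
    background spikes as well (never as channel events).
    """
    cfg = cfg or DetectorConfig()
    if trace.rate != cfg.analysis_rate:
        from .control import downsample

        trace = downsample(trace, cfg.analysis_rate)
    x = trace.samples
    n = len(x)
    if n == 0:
        return []
    dt = 1.0 / cfg.analysis_rate
    w = max(3, int(round(cfg.baseline_window / 1000.0 * cfg.analysis_rate)))
    onset_max = cfg.onset_window / 1000.0

    buf: deque = deque(maxlen=w)
    events: list[DetectionEvent] = []
    in_event = False
    onset_idx = 0
    b_frozen = 0.0
    extremum = 0.0
    last_conform_idx = 0

    for i in range(n):
        if not in_event:
            b = float(np.median(buf)) if buf else x[0]
            dev = x[i] - b
            if abs(dev) > cfg.amp_threshold and (i - last_conform_idx) * dt <= onset_max:
                in_event = True
                onset_idx = i
                b_frozen = b
                extremum = dev
                continue
            # not an event onset: the sample contributes to the baseline
            buf.append(x[i])
            if abs(dev) <= cfg.return_tolerance:
                last_conform_idx = i
        else:
            dev = x[i] - b_frozen
            if abs(dev) > abs(extremum):
                extremum = dev
            dur = (i - onset_idx) * dt
            if abs(dev) <= cfg.return_tolerance:
                kind = (
                    EventKind.CHANNEL_EVENT
                    if cfg.return_min <= dur <= cfg.return_max
                    else EventKind.BACKGROUND_SPIKE
                )
                events.append(DetectionEvent(
                    onset_t=trace.t0 + onset_idx * dt,
                    end_t=trace.t0 + i * dt,
                    amplitude=extremum,
                    kind=kind,
                ))
                in_event = False
                last_conform_idx = i
                buf.append(x[i])
            elif dur > cfg.return_max:
                # never returned: sustained level change, not a channel event
                events.append(DetectionEvent(
                    onset_t=trace.t0 + onset_idx * dt,
                    end_t=trace.t0 + i * dt,
                    amplitude=extremum,
                    kind=EventKind.BACKGROUND_SPIKE,
                ))
                in_event = False
                buf.append(x[i])
    return events


def detect_contact(chunk: CurrentTrace, cfg: Optional[ContactConfig] = None) -> Optional[float]:
    """Absolute time of the first |I| >= contact_threshold crossing, if any."""
    cfg = cfg or ContactConfig()
    hit = np.abs(chunk.samples) >= cfg.contact_threshold
    if not hit.any():
        return None
    return chunk.t0 + int(np.argmax(hit)) / chunk.rate


def detect_rupture(chunk: CurrentTrace, cfg: Optional[ContactConfig] = None) -> bool:
    """True if |I| stays >= sustained_threshold for >= sustained_dur anywhere."""
    cfg = cfg or ContactConfig()
    above = np.abs(chunk.samples) >= cfg.sustained_threshold
    need = int(round(cfg.sustained_dur * chunk.rate))
    if need <= 0 or not above.any():
        return False
    # longest run of True
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = edges[1::2] - edges[::2]
    return bool(runs.max() >= need)


def decide_window(events: list[DetectionEvent], window: float = 2.0) -> bool:
    """True iff at least one channel event was recognized within the window."""
    return any(e.kind is EventKind.CHANNEL_EVENT for e in events)
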