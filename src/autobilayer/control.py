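"""Feedback state machine driving the simulated probe.

Control flow: descend continuously at ``descent_speed`` until a contact
transient is detected; hold for ``contact_pause`` seconds; then advance in
``step_size`` increments every ``step_interval`` seconds, analyzing each
interval's current chunk at the analysis rate, until channel currents are
recognized (DETECTED_HOLD), a rupture signature appears (ABORTED_RUPTURE) or
``max_depth`` is exceeded (FAILED_MAX_DEPTH).

Simulated time is advanced exclusively by the controller's reads, so runs are
fully reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .detect import (
    ContactConfig,
    DetectionEvent,
    DetectorConfig,
    decide_window,
    detect_channel_events,
    detect_contact,
    detect_rupture,
)
from .errors import InvalidParameterError
from .simulate import AcquisitionStream
from .trace import CurrentTrace

__all__ = [
    "Phase",
    "ControllerConfig",
    "DetectionRecord",
    "AnalysisWindow",
    "AcquisitionLog",
    "downsample",
    "run_acquisition",
]


class Phase(str, Enum):
    DESCENDING = "DESCENDING"
    CONTACT_PAUSE = "CONTACT_PAUSE"
    STEPPING = "STEPPING"
    DETECTED_HOLD = "DETECTED_HOLD"
    ABORTED_RUPTURE = "ABORTED_RUPTURE"
    FAILED_MAX_DEPTH = "FAILED_MAX_DEPTH"


TERMINAL_PHASES = {Phase.DETECTED_HOLD, Phase.ABORTED_RUPTURE, Phase.FAILED_MAX_DEPTH}


@dataclass
class ControllerConfig:
    descent_speed: float = 260.0  # µm/s
    contact_pause: float = 10.0  # s
    step_size: float = 10.0  # µm
    step_interval: float = 2.0  # s
    max_depth: float = 5000.0  # µm
    abort_on_rupture: bool = True
    search_voltage: float = -60.0  # mV
    descent_tick: float = 0.01  # s; contact-poll cadence during descent

    def __post_init__(self) -> None:
        for name in ("descent_speed", "contact_pause", "step_size",
                     "step_interval", "max_depth", "descent_tick"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "descent_speed": self.descent_speed,
            "contact_pause": self.contact_pause,
            "step_size": self.step_size,
            "step_interval": self.step_interval,
            "max_depth": self.max_depth,
            "abort_on_rupture": self.abort_on_rupture,
            "search_voltage": self.search_voltage,
            "descent_tick": self.descent_tick,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerConfig":
        return cls(**d)


@dataclass
class DetectionRecord:
    time: float  # s, end of the winning analysis window
    position: float  # µm
    events: list[DetectionEvent]


@dataclass
class AnalysisWindow:
    position: float  # µm
    trace: CurrentTrace  # analysis-rate chunk
    events: list[DetectionEvent]


@dataclass
class AcquisitionLog:
    """Timed record of one automated run."""

    transitions: list[tuple[float, Phase, float]] = field(default_factory=list)
    detection: Optional[DetectionRecord] = None
    windows: list[AnalysisWindow] = field(default_factory=list)

    @property
    def terminal_phase(self) -> Phase:
        return self.transitions[-1][1]

    @property
    def elapsed(self) -> float:
        return self.transitions[-1][0]

    def events(self) -> list[DetectionEvent]:
        return [e for w in self.windows for e in w.events]


def downsample(trace: CurrentTrace, out_rate: float = 1000.0) -> CurrentTrace:
    """Block-mean decimation to an integer divisor of the input rate."""
    ratio = trace.rate / out_rate
    r = int(round(ratio))
    if r < 1 or abs(ratio - r) > 1e-9:
        raise InvalidParameterError(
            f"input rate {trace.rate} is not an integer multiple of {out_rate}"
        )
    if r == 1:
        return trace
    n = (len(trace.samples) // r) * r
    blocks = trace.samples[:n].reshape(-1, r)
    return CurrentTrace(
        blocks.mean(axis=1), rate=out_rate, voltage=trace.voltage,
        t0=trace.t0, meta=dict(trace.meta),
    )


def run_acquisition(
    stream: AcquisitionStream,
    detector_cfg: Optional[DetectorConfig] = None,
    contact_cfg: Optional[ContactConfig] = None,
    ctl: Optional[ControllerConfig] = None,
) -> AcquisitionLog:
    """Run the automated feedback acquisition on a stream until terminal."""
    detector_cfg = detector_cfg or DetectorConfig()
    contact_cfg = contact_cfg or ContactConfig()
    ctl = ctl or ControllerConfig()
    stream.voltage = ctl.search_voltage

    log = AcquisitionLog()
    pos = 0.0
    log.transitions.append((stream.time, Phase.DESCENDING, pos))

    # --- continuous descent until contact -------------------------------
    # position is derived from elapsed stream time (not accumulated) so that
    # the contact depth is hit at the exact arithmetic sample
    contact_time: Optional[float] = None
    t_start = stream.time
    while contact_time is None:
        pos = ctl.descent_speed * (stream.time - t_start)
        if pos >= ctl.max_depth:
            log.transitions.append((stream.time, Phase.FAILED_MAX_DEPTH, pos))
            return log
        end = min(pos + ctl.descent_speed * ctl.descent_tick, ctl.max_depth)
        dur = (end - pos) / ctl.descent_speed
        chunk = stream.read(dur, pos, end)
        hit = detect_contact(chunk, contact_cfg)
        if hit is not None:
            contact_time = hit
            pos = ctl.descent_speed * (hit - t_start)

    log.transitions.append((contact_time, Phase.CONTACT_PAUSE, pos))

    # --- pause at the contact position ----------------------------------
    remaining = contact_time + ctl.contact_pause - stream.time
    if remaining > 0:
        stream.read(remaining, pos, None)
    log.transitions.append((stream.time, Phase.STEPPING, pos))

    # --- step-and-analyze loop ------------------------------------------
    while True:
        if pos + ctl.step_size > ctl.max_depth:
            log.transitions.append((stream.time, Phase.FAILED_MAX_DEPTH, pos))
            return log
        pos += ctl.step_size
        raw = stream.read(ctl.step_interval, pos, None)
        chunk = downsample(raw, detector_cfg.analysis_rate)
        if ctl.abort_on_rupture and detect_rupture(chunk, contact_cfg):
            log.transitions.append((stream.time, Phase.ABORTED_RUPTURE, pos))
            return log
        events = detect_channel_events(chunk, detector_cfg)
        log.windows.append(AnalysisWindow(pos, chunk, events))
        if decide_window(events, ctl.step_interval):
            log.detection = DetectionRecord(stream.time, pos, events)
            log.transitions.append((stream.time, Phase.DETECTED_HOLD, pos))
            stream.position = pos
            return log
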