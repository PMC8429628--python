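"""Synthetic single-channel current traces and probe-descent acquisition streams.

The generative model is a two-state (closed <-> open) continuous-time Markov
chain per channel, with exponentially distributed dwell times.  The unitary
current obeys i = g * (V - E_rev) with g in pS, V and E_rev in mV, giving i in
pA after the 1/1000 unit conversion.  The number of channels incorporated in a
membrane follows a zero-truncated Poisson law (conditioning on at least one
channel having incorporated).

An :class:`AcquisitionStream` emulates the full automated run: quiet
open-circuit current while the probe descends, a large transient when the
probe first reaches the lipid-contact depth, bare-membrane baseline between
contact and bilayer formation, gated channel current once the probe is at or
below the formation depth, and a sustained large current if a rupture depth
is reached.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import InvalidParameterError
from .trace import CurrentTrace

__all__ = [
    "DEFAULT_RATE",
    "ANALYSIS_RATE",
    "ChannelScenario",
    "NoiseSpec",
    "DEFAULT_NOISE",
    "AcquisitionStreamSpec",
    "AcquisitionStream",
    "GatingProcess",
    "as_rng",
    "draw_dwell_sequence",
    "sample_channel_count",
    "simulate_gating",
    "render_noise",
    "render_trace",
    "list_presets",
    "load_preset",
]

DEFAULT_RATE = 10_000.0  #: archival sampling rate, Hz
ANALYSIS_RATE = 1_000.0  #: on-line analysis rate, Hz

#: sustained current emitted once the probe has broken the bilayer, pA
RUPTURE_AMPLITUDE = 1500.0

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Normalize an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ChannelScenario:
    """Generative parameters for one recording condition.

    Gating kinetics are over-determined by (open_prob, mean_open, mean_closed);
    any two may be given and the third is filled in from
    ``open_prob = mean_open / (mean_open + mean_closed)``.
    """

    name: str
    conductance_g: float  # pS
    reversal_E: float = 0.0  # mV
    open_prob: Optional[float] = None
    mean_open: Optional[float] = None  # ms
    mean_closed: Optional[float] = None  # ms
    channel_count_lambda: float = 0.6
    fixed_channel_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.conductance_g < 0:
            raise InvalidParameterError("conductance_g must be >= 0")
        given = [
            self.open_prob is not None,
            self.mean_open is not None,
            self.mean_closed is not None,
        ]
        if sum(given) < 2:
            raise InvalidParameterError(
                "need at least two of open_prob / mean_open / mean_closed"
            )
        if self.open_prob is None:
            self.open_prob = self.mean_open / (self.mean_open + self.mean_closed)
        elif self.mean_open is None:
            if not 0 < self.open_prob < 1:
                raise InvalidParameterError("open_prob must be in (0, 1) to derive dwell means")
            self.mean_open = self.mean_closed * self.open_prob / (1.0 - self.open_prob)
        elif self.mean_closed is None:
            if not 0 < self.open_prob < 1:
                raise InvalidParameterError("open_prob must be in (0, 1) to derive dwell means")
            self.mean_closed = self.mean_open * (1.0 - self.open_prob) / self.open_prob
        if self.mean_open <= 0 or self.mean_closed <= 0:
            raise InvalidParameterError("mean dwell times must be strictly positive")
        implied = self.mean_open / (self.mean_open + self.mean_closed)
        if abs(implied - self.open_prob) > 1e-9:
            raise InvalidParameterError(
                f"inconsistent kinetics: open_prob={self.open_prob} but "
                f"mean_open/(mean_open+mean_closed)={implied}"
            )
        if self.channel_count_lambda < 0:
            raise InvalidParameterError("channel_count_lambda must be >= 0")
        if self.fixed_channel_count is not None and self.fixed_channel_count < 1:
            raise InvalidParameterError("fixed_channel_count must be a positive integer")

    def unitary_current(self, voltage: float) -> float:
        """Open-level unitary current in pA at the given voltage (mV)."""
        return self.conductance_g * (voltage - self.reversal_E) / 1000.0

    def with_channels(self, count: int) -> "ChannelScenario":
        """Copy of this scenario with a fixed channel count."""
        return replace(self, fixed_channel_count=count)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "conductance_g": self.conductance_g,
            "reversal_E": self.reversal_E,
            "open_prob": self.open_prob,
            "mean_open": self.mean_open,
            "mean_closed": self.mean_closed,
            "channel_count_lambda": self.channel_count_lambda,
            "fixed_channel_count": self.fixed_channel_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelScenario":
        allowed = {
            "name", "conductance_g", "reversal_E", "open_prob", "mean_open",
            "mean_closed", "channel_count_lambda", "fixed_channel_count",
        }
        return cls(**{k: v for k, v in d.items() if k in allowed})


@dataclass
class NoiseSpec:
    """Additive recording-noise model: white Gaussian baseline noise, linear
    baseline drift, and sparse single-sample background spikes."""

    baseline_rms: float = 0.5  # pA
    drift_rate: float = 0.2  # pA/s
    spike_rate: float = 0.02  # events/s
    spike_amplitude: float = 3.0  # pA
    lowpass_cutoff: Optional[float] = None  # Hz; None = no filtering

    def __post_init__(self) -> None:
        if self.baseline_rms < 0:
            raise InvalidParameterError("baseline_rms must be >= 0")
        if self.spike_rate < 0:
            raise InvalidParameterError("spike_rate must be >= 0")
        for v in (self.baseline_rms, self.drift_rate, self.spike_rate,
                  self.spike_amplitude):
            if not np.isfinite(v):
                raise InvalidParameterError("noise parameters must be finite")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """Noise-free spec (exact level traces)."""
        return cls(baseline_rms=0.0, drift_rate=0.0, spike_rate=0.0,
                   spike_amplitude=0.0, lowpass_cutoff=None)

    def to_dict(self) -> dict:
        return {
            "baseline_rms": self.baseline_rms,
            "drift_rate": self.drift_rate,
            "spike_rate": self.spike_rate,
            "spike_amplitude": self.spike_amplitude,
            "lowpass_cutoff": self.lowpass_cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(**d)


DEFAULT_NOISE = NoiseSpec()


def draw_dwell_sequence(
    mean_open: float, mean_closed: float, duration: float, rng: SeedLike
) -> list[tuple[int, float]]:
    """Draw an alternating open/closed dwell sequence.

    Parameters
    ----------
    mean_open, mean_closed
        Mean dwell times in ms (strictly positive).
    duration
        Minimum total covered time in seconds.
    rng
        Seed or generator.

    Returns
    -------
    list of (state, duration_s) with state 1 = open, 0 = closed.  The initial
    state is drawn from the stationary distribution.  The sequence covers at
    least ``duration`` seconds; the final dwell is truncated at render time,
    not here.
    """
    if mean_open <= 0 or mean_closed <= 0:
        raise InvalidParameterError("mean dwell times must be > 0")
    if duration < 0:
        raise InvalidParameterError("duration must be >= 0")
    if duration == 0:
        return []
    rng = as_rng(rng)
    p_open = mean_open / (mean_open + mean_closed)
    state = 1 if rng.random() < p_open else 0
    means_s = {1: mean_open / 1000.0, 0: mean_closed / 1000.0}
    dwells: list[tuple[int, float]] = []
    total = 0.0
    while total < duration:
        d = rng.exponential(means_s[state])
        dwells.append((state, d))
        total += d
        state ^= 1
    return dwells


def sample_channel_count(lam: float, rng: SeedLike) -> int:
    """Draw a channel count from a zero-truncated Poisson(lam); always >= 1."""
    if lam <= 0:
        raise InvalidParameterError("lambda must be > 0")
    rng = as_rng(rng)
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return k


class GatingProcess:
    """Persistent two-state gating process for one channel.

    Dwell boundaries are generated lazily in absolute process time, so the
    process can be queried chunk by chunk with exact continuity.
    """

    def __init__(self, scenario: ChannelScenario, rng: SeedLike):
        self._rng = as_rng(rng)
        self._means_s = (scenario.mean_closed / 1000.0, scenario.mean_open / 1000.0)
        self._bounds: list[float] = [0.0]
        self._states: list[int] = []
        p_open = scenario.open_prob
        self._next_state = 1 if self._rng.random() < p_open else 0

    def _extend(self, t_end: float) -> None:
        while self._bounds[-1] <= t_end:
            state = self._next_state
            d = self._rng.exponential(self._means_s[state])
            self._states.append(state)
            self._bounds.append(self._bounds[-1] + d)
            self._next_state = state ^ 1

    def open_at(self, times: np.ndarray) -> np.ndarray:
        """0/1 open indicator at each (non-decreasing, absolute) time."""
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            return np.zeros(0, dtype=int)
        self._extend(float(times[-1]))
        idx = np.searchsorted(self._bounds, times, side="right") - 1
        states = np.asarray(self._states, dtype=int)
        return states[np.clip(idx, 0, len(states) - 1)]


def simulate_gating(
    scenario: ChannelScenario, duration: float, rate: float, rng: SeedLike
) -> np.ndarray:
    """Per-sample open-channel count for a fresh membrane.

    The channel count is ``fixed_channel_count`` if set, otherwise a
    zero-truncated Poisson draw with the scenario's lambda.
    """
    rng = as_rng(rng)
    n = int(round(duration * rate))
    if scenario.fixed_channel_count is not None:
        count = scenario.fixed_channel_count
    else:
        count = sample_channel_count(scenario.channel_count_lambda, rng)
    times = np.arange(n) / rate
    counts = np.zeros(n, dtype=int)
    for _ in range(count):
        counts += GatingProcess(scenario, rng).open_at(times)
    return counts


def render_noise(
    n: int,
    rate: float,
    noise: NoiseSpec,
    rng: SeedLike,
    t_offset: float = 0.0,
) -> np.ndarray:
    """Render ``n`` samples of additive noise (pA).

    Drift is linear in absolute time (``t_offset`` carries continuity across
    chunks).  Background spikes are single-sample excursions of the configured
    amplitude with random sign.
    """
    rng = as_rng(rng)
    out = np.zeros(n)
    if n == 0:
        return out
    t = t_offset + np.arange(n) / rate
    if noise.baseline_rms > 0:
        white = rng.normal(0.0, noise.baseline_rms, n)
        if noise.lowpass_cutoff is not None and noise.lowpass_cutoff < rate / 2:
            from scipy.signal import butter, sosfiltfilt

            sos = butter(4, noise.lowpass_cutoff, fs=rate, output="sos")
            white = sosfiltfilt(sos, white)
            sd = white.std()
            if sd > 0:
                white *= noise.baseline_rms / sd
        out += white
    out += noise.drift_rate * t
    if noise.spike_rate > 0 and noise.spike_amplitude != 0:
        n_spikes = rng.poisson(noise.spike_rate * n / rate)
        if n_spikes:
            idx = rng.integers(0, n, n_spikes)
            signs = rng.choice([-1.0, 1.0], n_spikes)
            np.add.at(out, idx, signs * noise.spike_amplitude)
    return out


def render_trace(
    scenario: ChannelScenario,
    voltage: float,
    duration: float,
    noise: Optional[NoiseSpec] = None,
    rate: float = DEFAULT_RATE,
    rng: SeedLike = 0,
) -> CurrentTrace:
    """Render a single fixed-voltage trace for a fresh membrane.

    The open-level unitary current i = g*(V - E_rev) is superposed per active
    channel; noise (if any) is added on top.  Outward currents are positive.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if rate <= 0:
        raise InvalidParameterError("rate must be > 0")
    rng = as_rng(rng)
    counts = simulate_gating(scenario, duration, rate, rng)
    samples = counts * scenario.unitary_current(voltage)
    if noise is not None:
        samples = samples + render_noise(len(counts), rate, noise, rng)
    return CurrentTrace(
        samples,
        rate=rate,
        voltage=voltage,
        meta={"scenario": scenario.name},
    )


@dataclass
class AcquisitionStreamSpec:
    """Geometry and content of a simulated probe-descent stream."""

    contact_depth: float  # µm
    formation_depth: float  # µm
    scenario: ChannelScenario
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    contact_transient_amp: float = 500.0  # pA
    contact_transient_dur: float = 50.0  # ms
    rupture_depth: Optional[float] = None  # µm

    def __post_init__(self) -> None:
        if self.formation_depth < self.contact_depth:
            raise InvalidParameterError("formation_depth must be >= contact_depth")
        if self.rupture_depth is not None and self.rupture_depth < self.formation_depth:
            raise InvalidParameterError("rupture_depth must be >= formation_depth")


class AcquisitionStream:
    """Chunked current source driven by an external controller clock.

    The controller owns simulated time: every :meth:`read` advances the stream
    by an exact number of samples, so identical command sequences reproduce
    identical streams bit for bit for a given seed.
    """

    def __init__(
        self,
        spec: AcquisitionStreamSpec,
        seed: SeedLike = 0,
        voltage: float = -60.0,
        rate: float = DEFAULT_RATE,
    ):
        self.spec = spec
        self.rate = float(rate)
        self.voltage = float(voltage)
        root = np.random.SeedSequence(seed) if not isinstance(
            seed, (np.random.Generator, np.random.SeedSequence)
        ) else seed
        if isinstance(root, np.random.Generator):
            self._noise_rng = root
            self._gate_rng = root
            self._count_rng = root
        else:
            s1, s2, s3 = root.spawn(3)
            self._noise_rng = np.random.default_rng(s1)
            self._gate_rng = np.random.default_rng(s2)
            self._count_rng = np.random.default_rng(s3)
        self._n_total = 0
        self.position = 0.0
        self._contact_time: Optional[float] = None
        self._formed_time: Optional[float] = None
        self._gates: Optional[list[GatingProcess]] = None
        self.channel_count: Optional[int] = None

    @property
    def time(self) -> float:
        """Current stream time in seconds (exact: total samples / rate)."""
        return self._n_total / self.rate

    def _ensure_channels(self) -> None:
        if self._gates is not None:
            return
        sc = self.spec.scenario
        if sc.fixed_channel_count is not None:
            self.channel_count = sc.fixed_channel_count
        else:
            self.channel_count = sample_channel_count(
                sc.channel_count_lambda, self._count_rng
            )
        self._gates = [GatingProcess(sc, self._gate_rng) for _ in range(self.channel_count)]

    def read(
        self,
        duration: float,
        pos_start: float,
        pos_end: Optional[float] = None,
    ) -> CurrentTrace:
        """Read the next chunk while the probe moves pos_start -> pos_end (µm)."""
        if duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        n = int(round(duration * self.rate))
        if n < 1:
            raise InvalidParameterError("duration shorter than one sample")
        t0 = self.time
        t = t0 + np.arange(n) / self.rate
        if pos_end is None or pos_end == pos_start:
            pos = np.full(n, pos_start)
        else:
            pos = pos_start + (pos_end - pos_start) * (np.arange(n) / n)
        spec = self.spec
        i = np.zeros(n)

        if self._contact_time is None:
            hit = pos >= spec.contact_depth
            if hit.any():
                self._contact_time = float(t[int(np.argmax(hit))])
        if self._contact_time is not None:
            ct = self._contact_time
            mask = (t >= ct) & (t < ct + spec.contact_transient_dur / 1000.0)
            i[mask] += spec.contact_transient_amp

        formed = pos >= spec.formation_depth
        if formed.any():
            self._ensure_channels()
            if self._formed_time is None:
                self._formed_time = float(t[int(np.argmax(formed))])
            gt = t[formed] - self._formed_time
            counts = np.zeros(int(formed.sum()), dtype=int)
            for g in self._gates:  # type: ignore[union-attr]
                counts += g.open_at(gt)
            i[formed] += counts * spec.scenario.unitary_current(self.voltage)

        if spec.rupture_depth is not None:
            rup = pos >= spec.rupture_depth
            if rup.any():
                i[rup] = RUPTURE_AMPLITUDE

        i += render_noise(n, self.rate, spec.noise, self._noise_rng, t_offset=t0)
        self._n_total += n
        self.position = float(pos[-1]) if pos_end is not None else pos_start
        return CurrentTrace(
            i, rate=self.rate, voltage=self.voltage, t0=t0,
            meta={"scenario": spec.scenario.name},
        )

    def record(self, duration: float, voltage: Optional[float] = None) -> CurrentTrace:
        """Record a fixed-voltage trace at the current (held) probe position."""
        if voltage is not None:
            self.voltage = float(voltage)
        return self.read(duration, self.position, None)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def list_presets() -> list[str]:
    """Names of the scenario presets shipped with the package."""
    pkg = resources.files("autobilayer") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))


def load_preset(name: str) -> tuple[ChannelScenario, NoiseSpec]:
    """Load a shipped preset by name, or any scenario JSON by path."""
    path = Path(name)
    if path.suffix == ".json" and path.exists():
        payload = json.loads(path.read_text())
    else:
        res = resources.files("autobilayer") / "presets" / f"{name}.json"
        try:
            payload = json.loads(res.read_text())
        except FileNotFoundError:
            raise InvalidParameterError(
                f"unknown preset {name!r}; available: {', '.join(list_presets())}"
            ) from None
    noise = NoiseSpec.from_dict(payload.pop("noise", {}))
    return ChannelScenario.from_dict(payload), noise
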