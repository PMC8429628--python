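"""Core trace container.

Currents are in pA with outward currents positive and inward currents
negative; voltages in mV; time in seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CurrentTrace"]


@dataclass(eq=False)
class CurrentTrace:
    """A uniformly sampled current recording.

    Parameters
    ----------
    samples
        Current samples in pA.
    rate
        Sampling rate in Hz.
    voltage
        Holding voltage in mV.
    t0
        Absolute time of the first sample in seconds.
    meta
        Free-form provenance (scenario name, seed, condition, ...).
    """

    samples: np.ndarray
    rate: float
    voltage: float = 0.0
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) / self.rate

    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(len(self.samples)) / self.rate

    def allclose(self, other: "CurrentTrace", atol: float = 1e-6) -> bool:
        """Equality up to float formatting of samples; rate/voltage exact."""
        return (
            len(self) == len(other)
            and self.rate == other.rate
            and self.voltage == other.voltage
            and bool(np.allclose(self.samples, other.samples, atol=atol, rtol=0))
        )
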