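"""Quantitative single-channel analysis.

Idealization assigns each sample an open-level count k by half-amplitude
thresholding: a sample belongs to level k when its current lies within half a
unitary amplitude of baseline + k*u.  Baseline drift is tracked by estimating,
block by block, the phase of the current distribution folded modulo |u|
(levels are spaced exactly u apart, so they share one lattice phase); the
phase is unwrapped across blocks and interpolated per sample.  Dwells shorter
than two samples are merged into their neighbours.

Downstream: per-voltage unitary amplitudes, ordinary-least-squares I-V fits
(slope conductance in pS), membrane area from capacitance, and Welch's t-test
condition comparisons.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, medfilt
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidParameterError, NoEventsError
from .simulate import (
    DEFAULT_NOISE,
    DEFAULT_RATE,
    ChannelScenario,
    NoiseSpec,
    SeedLike,
    as_rng,
    render_trace,
)
from .trace import CurrentTrace

__all__ = [
    "DEFAULT_VOLTAGE_GRID",
    "IdealizedTrace",
    "IVDataset",
    "IVFit",
    "MembraneGeometry",
    "ConditionComparison",
    "idealize",
    "unitary_amplitude",
    "estimate_unitary_guess",
    "measure_unitary",
    "build_iv",
    "fit_iv",
    "recover_conductance",
    "membrane_area",
    "count_open_levels",
    "classify_channel_count",
    "welch_t_from_summary",
    "compare_conditions",
]

#: default I-V protocol: -100..+100 mV in 20 mV steps
DEFAULT_VOLTAGE_GRID: tuple[float, ...] = tuple(float(v) for v in range(-100, 101, 20))


@dataclass
class IdealizedTrace:
    """Piecewise-constant open-level representation of a trace."""

    levels: np.ndarray  # per-sample open-level count, int >= 0
    dwells: list[tuple[int, float]]  # (level, duration_s)
    unitary_amplitude: float  # pA, signed (the guess used for thresholding)
    rate: float
    baseline: np.ndarray  # per-sample level-0 current, pA

    def duration(self) -> float:
        return len(self.levels) / self.rate


def _runs(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, run_length) for consecutive runs."""
    if len(levels) == 0:
        return []
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(levels)]))
    return [(int(levels[s]), int(e - s)) for s, e in zip(starts, ends)]


def _merge_short_runs(runs: list[tuple[int, int]], min_len: int) -> list[tuple[int, int]]:
    """Merge runs shorter than min_len into the longer adjacent run."""
    runs = list(runs)
    while len(runs) > 1:
        idx = None
        for i, (_, ln) in enumerate(runs):
            if ln < min_len:
                idx = i
                break
        if idx is None:
            break
        level, ln = runs[idx]
        left = runs[idx - 1] if idx > 0 else None
        right = runs[idx + 1] if idx + 1 < len(runs) else None
        if left is not None and (right is None or left[1] >= right[1]):
            runs[idx - 1] = (left[0], left[1] + ln)
        else:
            runs[idx + 1] = (right[0], right[1] + ln)
        del runs[idx]
        # coalesce equal neighbours
        out: list[tuple[int, int]] = []
        for lev, length in runs:
            if out and out[-1][0] == lev:
                out[-1] = (lev, out[-1][1] + length)
            else:
                out.append((lev, length))
        runs = out
    return runs


def _lattice_offset(x: np.ndarray, au: float, rate: float, block_s: float) -> np.ndarray:
    """Per-sample offset of the level lattice (tracks slow baseline drift).

    All occupied levels sit at offset + k*u, so the offset is the circular
    mean phase of x mod au, estimated per block and unwrapped for continuity.
    """
    n = len(x)
    nb = max(1, int(round(n / (block_s * rate))))
    blocks = np.array_split(np.arange(n), nb)
    centers = []
    offsets: list[float] = []
    prev: Optional[float] = None
    for idx in blocks:
        z = np.exp(2j * np.pi * x[idx] / au).mean()
        ph = np.angle(z) / (2 * np.pi) * au
        c = ph if prev is None else ph + au * round((prev - ph) / au)
        offsets.append(c)
        prev = c
        centers.append(idx.mean())
    if nb == 1:
        return np.full(n, offsets[0])
    return np.interp(np.arange(n), centers, offsets)


def idealize(
    trace: CurrentTrace,
    unitary_guess: float,
    *,
    block_s: float = 0.5,
    min_dwell_samples: int = 2,
) -> IdealizedTrace:
    """Half-amplitude threshold idealization with drift-tracking baseline.

    ``unitary_guess`` is the signed approximate unitary current (pA); a sample
    is assigned level k when it lies within |u|/2 of baseline + k*u.  Dwells
    shorter than ``min_dwell_samples`` are merged into neighbours.
    """
    if unitary_guess == 0:
        raise InvalidParameterError("unitary_guess must be non-zero")
    x = np.asarray(trace.samples, dtype=float)
    n = len(x)
    if n == 0:
        return IdealizedTrace(np.zeros(0, dtype=int), [], float(unitary_guess),
                              trace.rate, np.zeros(0))
    au = abs(unitary_guess)
    lattice = _lattice_offset(x, au, trace.rate, block_s)
    k = np.rint((x - lattice) / unitary_guess).astype(int)
    if n >= 3:
        k = medfilt(k.astype(float), 3).astype(int)
    runs = _merge_short_runs(_runs(k), min_dwell_samples)
    levels = np.repeat([lev for lev, _ in runs], [ln for _, ln in runs])
    kmin = int(levels.min())
    levels = levels - kmin
    baseline = lattice + kmin * unitary_guess
    dwells = [(lev, ln / trace.rate) for lev, ln in _runs(levels)]
    return IdealizedTrace(levels.astype(int), dwells, float(unitary_guess),
                          trace.rate, baseline)


def unitary_amplitude(ideal: IdealizedTrace, trace: CurrentTrace) -> float:
    """Signed unitary amplitude from an idealized trace.

    For a two-level trace this is the mean open-level current minus the mean
    closed-level current.  With more levels, the per-level mean currents are
    fit against the level index by weighted least squares and the slope is
    returned (identical to the two-level definition when only levels 0 and 1
    are occupied).
    """
    levels = ideal.levels
    if len(levels) != len(trace.samples):
        raise InvalidParameterError("idealization does not match trace length")
    if not (levels >= 1).any():
        raise NoEventsError("no open dwells in idealization")
    resid = np.asarray(trace.samples, dtype=float) - ideal.baseline
    ks, counts = np.unique(levels, return_counts=True)
    means = np.array([resid[levels == kk].mean() for kk in ks])
    if len(ks) == 1:
        # no closed reference: trust the baseline estimate
        return float(means[0] / ks[0])
    wls = np.polyfit(ks.astype(float), means, 1, w=np.sqrt(counts))
    return float(wls[0])


def estimate_unitary_guess(
    trace: CurrentTrace,
    reversal_E: float = 0.0,
    *,
    bin_width: float = 0.1,
    smooth_pa: float = 0.25,
    min_peak_fraction: float = 0.03,
    min_separation: float = 0.8,
) -> Optional[float]:
    """Data-driven unitary-amplitude guess from the all-points histogram.

    The trace is linearly detrended, histogrammed, smoothed, and the median
    spacing of histogram peaks is returned with the sign of (V - E_rev).
    Returns None when openings are not resolvable (fewer than two peaks, or
    V == E_rev so no current direction is defined).
    """
    dv = trace.voltage - reversal_E
    if dv == 0:
        return None
    x = np.asarray(trace.samples, dtype=float)
    if len(x) < 10:
        return None
    t = np.arange(len(x))
    coef = np.polyfit(t, x, 1)
    xd = x - np.polyval(coef, t)
    lo, hi = xd.min(), xd.max()
    if hi - lo < bin_width:
        return None
    # pad the range so peaks never sit on the array boundary
    edges = np.arange(lo - 1.0, hi + 1.0 + bin_width, bin_width)
    hist, _ = np.histogram(xd, bins=edges)
    smooth = gaussian_filter1d(hist.astype(float), sigma=max(1.0, smooth_pa / bin_width))
    dist = max(1, int(round(min_separation / bin_width)))
    peaks, _ = find_peaks(smooth, prominence=min_peak_fraction * smooth.max(),
                          distance=dist)
    if len(peaks) < 2:
        return None
    centers = (edges[:-1] + edges[1:]) / 2.0
    spacing = float(np.median(np.diff(centers[peaks])))
    return math.copysign(spacing, dv)


def measure_unitary(
    trace: CurrentTrace,
    reversal_E: float = 0.0,
    guess: Optional[float] = None,
) -> Optional[float]:
    """Unitary amplitude of one trace, or None if openings are unresolvable."""
    if guess is None:
        guess = estimate_unitary_guess(trace, reversal_E)
    if guess is None or guess == 0:
        return None
    ideal = idealize(trace, guess)
    try:
        return unitary_amplitude(ideal, trace)
    except NoEventsError:
        return None


@dataclass
class IVDataset:
    """Per-voltage unitary amplitudes with per-point trace counts."""

    voltages: np.ndarray  # mV
    amplitudes: np.ndarray  # pA
    n_traces: np.ndarray  # traces averaged per point

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.n_traces = np.asarray(self.n_traces, dtype=int)


@dataclass
class IVFit:
    """OLS line through (V, i) pairs; slope expressed as conductance in pS."""

    slope_conductance: float  # pS
    intercept: float  # pA
    r2: float
    se_slope: float  # pS
    n_points: int


@dataclass
class MembraneGeometry:
    capacitance: float  # nF
    specific_capacitance: float  # µF/cm²
    area: float  # mm²

    @classmethod
    def from_capacitance(cls, capacitance: float, specific_capacitance: float) -> "MembraneGeometry":
        return cls(capacitance, specific_capacitance,
                   membrane_area(capacitance, specific_capacitance))


def build_iv(
    traces: Iterable[CurrentTrace],
    reversal_E: float = 0.0,
) -> IVDataset:
    """Per-voltage mean unitary amplitudes from a set of traces.

    Voltages at which no trace yields a resolvable unitary amplitude are
    omitted from the dataset.
    """
    per_voltage: dict[float, list[float]] = {}
    for tr in traces:
        u = measure_unitary(tr, reversal_E)
        if u is None:
            continue
        per_voltage.setdefault(tr.voltage, []).append(u)
    if not per_voltage:
        raise InsufficientDataError("no voltage yielded a resolvable unitary amplitude")
    vs = sorted(per_voltage)
    return IVDataset(
        voltages=np.array(vs),
        amplitudes=np.array([np.mean(per_voltage[v]) for v in vs]),
        n_traces=np.array([len(per_voltage[v]) for v in vs]),
    )


def fit_iv(data: IVDataset) -> IVFit:
    """Unweighted OLS I-V fit; slope converted from pA/mV to pS (x1000)."""
    v = data.voltages
    if len(np.unique(v)) < 2:
        raise InsufficientDataError("need >= 2 distinct voltages for an I-V fit")
    res = linregress(v, data.amplitudes)
    return IVFit(
        slope_conductance=float(res.slope) * 1000.0,
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        se_slope=float(res.stderr) * 1000.0 if res.stderr is not None else float("nan"),
        n_points=len(v),
    )


def recover_conductance(
    scenario: ChannelScenario,
    noise: Optional[NoiseSpec] = DEFAULT_NOISE,
    seed: SeedLike = 0,
    voltages: Sequence[float] = DEFAULT_VOLTAGE_GRID,
    duration: float = 30.0,
    rate: float = DEFAULT_RATE,
) -> tuple[IVFit, IVDataset]:
    """Full simulate -> idealize -> amplitude -> fit pipeline for one scenario."""
    rng = as_rng(seed)
    traces = [
        render_trace(scenario, v, duration, noise, rate, rng) for v in voltages
    ]
    data = build_iv(traces, reversal_E=scenario.reversal_E)
    return fit_iv(data), data


def membrane_area(capacitance: float, specific_capacitance: float) -> float:
    """Bilayer area in mm² from capacitance (nF) and specific capacitance (µF/cm²).

    area [mm²] = C [nF] * 1e-9 / (c [µF/cm²] * 1e-6 / 100) = 0.1 * C / c.
    """
    if specific_capacitance <= 0:
        raise InvalidParameterError("specific_capacitance must be > 0")
    if capacitance < 0:
        raise InvalidParameterError("capacitance must be >= 0")
    return 0.1 * capacitance / specific_capacitance


def count_open_levels(ideal: IdealizedTrace) -> int:
    """Maximum simultaneous open-level count."""
    if len(ideal.levels) == 0:
        return 0
    return int(ideal.levels.max())


def classify_channel_count(count: int) -> str:
    """'none' / 'single' / 'double' / 'multiple' per maximum open level."""
    if count <= 0:
        return "none"
    if count == 1:
        return "single"
    if count == 2:
        return "double"
    return "multiple"


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> tuple[float, float]:
    """Welch's t statistic and Welch-Satterthwaite degrees of freedom.

    t = (mean1 - mean2) / sqrt(sd1²/n1 + sd2²/n2).  With zero pooled variance
    the statistic is 0 for equal means and signed infinity otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise InvalidParameterError("standard deviations must be >= 0")
    v1 = sd1 ** 2 / n1
    v2 = sd2 ** 2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2)
        return math.copysign(math.inf, mean1 - mean2), float("nan")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    denom = 0.0
    if v1 > 0:
        denom += v1 ** 2 / (n1 - 1)
    if v2 > 0:
        denom += v2 ** 2 / (n2 - 1)
    df = (v1 + v2) ** 2 / denom
    return float(t), float(df)


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass
class ConditionComparison:
    group_a: GroupSummary
    group_b: GroupSummary
    welch_t: float
    welch_df: float
    conductance_ratio: float  # mean_b / mean_a


def _conductances(values: Sequence[Union[float, IVFit]]) -> np.ndarray:
    out = []
    for v in values:
        out.append(v.slope_conductance if isinstance(v, IVFit) else float(v))
    return np.array(out, dtype=float)


def compare_conditions(
    fits_a: Sequence[Union[float, IVFit]],
    fits_b: Sequence[Union[float, IVFit]],
) -> ConditionComparison:
    """Compare per-recording conductances between two conditions.

    Reports group means/SDs, the ratio mean_b/mean_a and Welch's t-test.
    """
    ga = _conductances(fits_a)
    gb = _conductances(fits_b)
    if len(ga) < 2 or len(gb) < 2:
        raise InsufficientDataError("need >= 2 per-recording conductances per condition")
    sa = GroupSummary(float(ga.mean()), float(ga.std(ddof=1)), len(ga))
    sb = GroupSummary(float(gb.mean()), float(gb.std(ddof=1)), len(gb))
    t, df = welch_t_from_summary(sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n)
    ratio = sb.mean / sa.mean if sa.mean != 0 else float("nan")
    return ConditionComparison(sa, sb, t, df, ratio)
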