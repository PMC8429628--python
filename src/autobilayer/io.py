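"""Trace and configuration file I/O.

Two plain-text trace formats are supported:

* **ATF** (Axon Text Format 1.0): interchange format understood by common
  electrophysiology software.  Header: ``ATF<TAB>1.0``, a record-count line,
  quoted optional-header records, a column-title line, then tab-separated
  Time (s) / Current (pA) rows.
* **TSV dialect**: ``#``-prefixed ``key: value`` header lines followed by a
  two-column ``time_s<TAB>current_pA`` table.

Times are written with 6 decimal places and currents with 4; a write->read
round trip preserves samples to 1e-6 pA (well within 1e-4 formatting), and
rate/voltage exactly.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import FormatError
from .trace import CurrentTrace

__all__ = [
    "write_atf",
    "read_atf",
    "write_tsv",
    "read_tsv",
    "read_trace",
    "write_trace",
    "load_json_config",
    "dump_json_config",
    "generate_fixtures",
]

_TIME_FMT = "%.6f"
_CURR_FMT = "%.4f"


def _infer_rate(times: np.ndarray, path: Path) -> float:
    if len(times) < 2:
        raise FormatError(f"{path}: cannot infer rate from fewer than 2 samples")
    steps = np.diff(times)
    step = float(np.median(steps))
    if step <= 0 or not np.allclose(steps, step, rtol=0, atol=1e-9):
        raise FormatError(f"{path}: non-uniform time column")
    return 1.0 / step


def write_atf(trace: CurrentTrace, path: Union[str, Path]) -> None:
    """Write a trace as Axon Text Format 1.0."""
    path = Path(path)
    records = [
        f'"Rate (Hz)={trace.rate:g}"',
        f'"Voltage (mV)={trace.voltage:g}"',
        f'"Start (s)={trace.t0:g}"',
    ]
    for key, val in trace.meta.items():
        records.append(f'"Meta:{key}={val}"')
    lines = [
        "ATF\t1.0",
        f"{len(records)}\t2",
        *records,
        '"Time (s)"\t"Current (pA)"',
    ]
    t = trace.times()
    for ti, ci in zip(t, trace.samples):
        lines.append(f"{_TIME_FMT % ti}\t{_CURR_FMT % ci}")
    path.write_text("\n".join(lines) + "\n")


def read_atf(path: Union[str, Path]) -> CurrentTrace:
    """Read an ATF 1.0 file with Time/Current columns."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise FormatError(f"{path}: line 1 is not an ATF signature")
    try:
        n_rec, n_cols = (int(x) for x in lines[1].split("\t"))
    except (IndexError, ValueError):
        raise FormatError(f"{path}: line 2 is not a valid ATF dimension line") from None
    if n_cols != 2:
        raise FormatError(f"{path}: expected 2 columns, found {n_cols}")
    rate: Optional[float] = None
    voltage = 0.0
    t0 = 0.0
    meta: dict = {}
    for lineno, rec in enumerate(lines[2:2 + n_rec], start=3):
        body = rec.strip().strip('"')
        if "=" not in body:
            raise FormatError(f"{path}: malformed header record at line {lineno}: {rec!r}")
        key, _, val = body.partition("=")
        if key == "Rate (Hz)":
            rate = float(val)
        elif key == "Voltage (mV)":
            voltage = float(val)
        elif key == "Start (s)":
            t0 = float(val)
        elif key.startswith("Meta:"):
            meta[key[5:]] = val
    data_lines = lines[3 + n_rec:]
    times, currents = [], []
    for lineno, row in enumerate(data_lines, start=4 + n_rec):
        if not row.strip():
            continue
        parts = row.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed data row at line {lineno}: {row!r}")
        times.append(float(parts[0]))
        currents.append(float(parts[1]))
    times_arr = np.array(times)
    if rate is None:
        rate = _infer_rate(times_arr, path)
    elif len(times_arr) >= 2:
        _ = _infer_rate(times_arr, path)  # validates uniformity
    return CurrentTrace(np.array(currents), rate=rate, voltage=voltage, t0=t0, meta=meta)


def write_tsv(trace: CurrentTrace, path: Union[str, Path]) -> None:
    """Write a trace in the package's native TSV dialect."""
    path = Path(path)
    lines = [
        "# format: autobilayer-tsv 1",
        f"# rate_hz: {trace.rate:g}",
        f"# voltage_mv: {trace.voltage:g}",
        f"# t0_s: {trace.t0:g}",
    ]
    for key, val in trace.meta.items():
        lines.append(f"# meta {key}: {val}")
    lines.append("time_s\tcurrent_pA")
    for ti, ci in zip(trace.times(), trace.samples):
        lines.append(f"{_TIME_FMT % ti}\t{_CURR_FMT % ci}")
    path.write_text("\n".join(lines) + "\n")


def read_tsv(path: Union[str, Path]) -> CurrentTrace:
    """Read the TSV dialect (rate inferred from the time column if absent)."""
    path = Path(path)
    rate: Optional[float] = None
    voltage = 0.0
    t0 = 0.0
    meta: dict = {}
    times, currents = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            key, _, val = body.partition(":")
            key = key.strip()
            val = val.strip()
            if key == "rate_hz":
                rate = float(val)
            elif key == "voltage_mv":
                voltage = float(val)
            elif key == "t0_s":
                t0 = float(val)
            elif key.startswith("meta "):
                meta[key[5:]] = val
            continue
        if line.startswith("time_s"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed row at line {lineno}: {line!r}")
        try:
            times.append(float(parts[0]))
            currents.append(float(parts[1]))
        except ValueError:
            raise FormatError(f"{path}: non-numeric row at line {lineno}: {line!r}") from None
    times_arr = np.array(times)
    if rate is None:
        rate = _infer_rate(times_arr, path)
    elif len(times_arr) >= 2:
        _ = _infer_rate(times_arr, path)
    return CurrentTrace(np.array(currents), rate=rate, voltage=voltage, t0=t0, meta=meta)


def read_trace(path: Union[str, Path]) -> CurrentTrace:
    """Read a trace file, sniffing ATF vs TSV from the first line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("ATF"):
        return read_atf(path)
    if first.startswith("#") or first.startswith("time_s"):
        return read_tsv(path)
    raise FormatError(f"{path}: unrecognized trace format (first line {first!r})")


def write_trace(trace: CurrentTrace, path: Union[str, Path]) -> None:
    """Write a trace, choosing the format from the file extension."""
    path = Path(path)
    if path.suffix.lower() == ".atf":
        write_atf(trace, path)
    else:
        write_tsv(trace, path)


def load_json_config(path: Union[str, Path]) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from None


def dump_json_config(payload: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Canonical fixture generation
# ---------------------------------------------------------------------------

PULSE_AMPLITUDES = (1.0, 1.9, 2.1, 4.0, 5.0, 10.0)  # pA
PULSE_DURATIONS = (0.005, 0.02, 0.5, 0.99, 1.5)  # s


def make_pulse_trace(
    amplitude: float,
    duration: float,
    rate: float = 1000.0,
    pre: float = 0.5,
    post: float = 1.2,
) -> CurrentTrace:
    """Noiseless square pulse on a flat zero baseline."""
    n_pre = int(round(pre * rate))
    n_pulse = int(round(duration * rate))
    n_post = int(round(post * rate))
    x = np.concatenate([
        np.zeros(n_pre), np.full(n_pulse, amplitude), np.zeros(n_post)
    ])
    return CurrentTrace(x, rate=rate, voltage=0.0,
                        meta={"pulse_amplitude_pa": amplitude,
                              "pulse_duration_s": duration})


def generate_fixtures(seed: int, out_dir: Union[str, Path]) -> Path:
    """Write the canonical test fixture set; returns the manifest path.

    Fixtures: the noiseless pulse grid for the detector-rule oracle, preset
    traces at +/-100 mV, a three-channel trace, and a manifest recording the
    ground-truth parameters.  Identical seeds give byte-identical output.
    """
    from .simulate import NoiseSpec, list_presets, load_preset, render_trace

    out = Path(out_dir)
    (out / "pulses").mkdir(parents=True, exist_ok=True)
    (out / "presets").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "pulses": [], "presets": {}, "multichannel": {}}

    for amp in PULSE_AMPLITUDES:
        for dur in PULSE_DURATIONS:
            name = f"pulse_a{amp:g}_d{dur:g}.tsv"
            write_tsv(make_pulse_trace(amp, dur), out / "pulses" / name)
            manifest["pulses"].append({
                "file": f"pulses/{name}",
                "amplitude_pa": amp,
                "duration_s": dur,
                "is_channel_event": bool(amp > 2.0 and 0.01 <= dur <= 1.0),
            })

    ss = np.random.SeedSequence(seed)
    for preset, child in zip(list_presets(), ss.spawn(len(list_presets()) + 1)):
        scenario, noise = load_preset(preset)
        for voltage in (-100.0, 100.0):
            rng = np.random.default_rng([child.entropy, int(abs(voltage)),
                                         int(voltage > 0)])
            tr = render_trace(scenario, voltage, 5.0, noise, 1000.0, rng)
            fname = f"{preset}_{'pos' if voltage > 0 else 'neg'}100.tsv"
            write_tsv(tr, out / "presets" / fname)
        manifest["presets"][preset] = scenario.to_dict() | {"noise": noise.to_dict()}

    scenario, _ = load_preset("kcsa_e71a_decane")
    tri = scenario.with_channels(3)
    rng = np.random.default_rng([seed, 333])
    tr = render_trace(tri, 100.0, 5.0, NoiseSpec.none(), 1000.0, rng)
    write_tsv(tr, out / "multichannel.tsv")
    manifest["multichannel"] = {
        "file": "multichannel.tsv", "channels": 3,
        "unitary_pa": tri.unitary_current(100.0),
    }

    manifest_path = out / "manifest.json"
    dump_json_config(manifest, manifest_path)
    return manifest_path
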