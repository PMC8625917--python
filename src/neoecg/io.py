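"""Record I/O: WFDB signal records, CSV signals, annotations, alarm logs.

WFDB support is a self-contained reader/writer for the subset the pipeline
touches: text ``.hea`` headers, format-16 (little-endian int16) ``.dat``
signal files and MIT-format binary annotation files.  Sample values are
converted to physical units (mV) with the header's gain/baseline, so the
rest of the package never sees ADC codes.

CSV records use two columns ``time_s, amplitude_mV`` with a header row
(UTF-8); the sampling rate is supplied by the caller since a CSV carries
no authoritative header.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ECGSignal",
    "read_ecg",
    "write_csv",
    "write_wfdb",
    "read_annotations",
    "write_annotations",
    "write_alarms_jsonl",
    "read_alarms_jsonl",
]


@dataclass
class ECGSignal:
    """Uniformly sampled single-lead ECG in physical units (mV)."""

    samples: np.ndarray
    fs: float
    adc_resolution: int = 16
    record_name: str = ""
    start_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if not 8 <= self.adc_resolution <= 32:
            raise ValueError(
                f"adc_resolution must be in [8, 32], got {self.adc_resolution}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def window(self, start_s: float, duration_s: float) -> "ECGSignal":
        """Half-open window [start_s, start_s + duration_s)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round((start_s + duration_s) * self.fs))
        i0, i1 = max(0, i0), min(self.samples.size, i1)
        return ECGSignal(self.samples[i0:i1].copy(), self.fs,
                         self.adc_resolution, self.record_name,
                         self.start_offset + i0 / self.fs)


# ---------------------------------------------------------------- WFDB ----

@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    adc_res: int


def _parse_header(path: Path):
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty WFDB header: {path}")
    rec = lines[0].split()
    if len(rec) < 3:
        raise ValueError(f"malformed WFDB record line: {lines[0]!r}")
    name = rec[0].split("/")[0]
    nsig = int(rec[1])
    fs = float(rec[2].split("/")[0])
    nsamp = int(rec[3]) if len(rec) > 3 else None
    specs = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        if len(f) < 2:
            raise ValueError(f"malformed WFDB signal line: {ln!r}")
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = f[2] if len(f) > 2 else "200"
        units = "mV"
        if "/" in gain_field:
            gain_field, units = gain_field.split("/", 1)
        baseline = 0
        if "(" in gain_field:
            gain_field, rest = gain_field.split("(", 1)
            baseline = int(rest.rstrip(")"))
        gain = float(gain_field) if float(gain_field) != 0 else 200.0
        adc_res = int(f[3]) if len(f) > 3 else 12
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if "(" not in (f[2] if len(f) > 2 else ""):
            baseline = adc_zero
        specs.append(_SignalSpec(f[0], fmt, gain, baseline, units, adc_res))
    return name, nsig, fs, nsamp, specs


def _read_dat(path: Path, fmt: int, nsig: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (b.size // 3)].reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        data = np.column_stack([s0, s1]).ravel()
        data = np.where(data > 2047, data - 4096, data)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    usable = nsig * (data.size // nsig)
    return data[:usable].reshape(-1, nsig)


def read_ecg(path, format: str = "wfdb", channel: int = 0,
             window: tuple[float, float] | None = None,
             fs: float | None = None,
             adc_resolution: int = 16) -> ECGSignal:
    """Read one channel of a record; optional half-open (start_s, duration_s).

    ``format="wfdb"`` expects the header path (or record stem) of a
    ``.hea``/``.dat`` pair; ``format="csv"`` expects a two-column
    ``time_s, amplitude_mV`` file and an explicit ``fs``.
    """
    path = Path(path)
    if format == "wfdb":
        hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
        if not hea.exists():
            raise FileNotFoundError(f"WFDB header not found: {hea}")
        name, nsig, fs_h, _, specs = _parse_header(hea)
        if not 0 <= channel < nsig:
            raise IndexError(f"channel {channel} out of range for {nsig} signals")
        spec = specs[channel]
        dat = hea.parent / spec.file_name
        if not dat.exists():
            raise FileNotFoundError(f"WFDB signal file not found: {dat}")
        adc = _read_dat(dat, spec.fmt, nsig)[:, channel]
        physical = (adc - spec.baseline) / spec.gain
        sig = ECGSignal(physical, fs_h, spec.adc_res, record_name=name)
    elif format == "csv":
        if not path.exists():
            raise FileNotFoundError(f"CSV record not found: {path}")
        if fs is None:
            raise ValueError("fs is required when reading CSV records")
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("CSV record needs (time_s, amplitude_mV) columns")
        sig = ECGSignal(df.iloc[:, 1].to_numpy(dtype=float), fs,
                        adc_resolution, record_name=path.stem)
    else:
        raise ValueError(f"unknown format {format!r}; use 'wfdb' or 'csv'")
    if window is not None:
        sig = sig.window(*window)
    return sig


def write_csv(signal: ECGSignal, path) -> None:
    """Two-column CSV (time_s, amplitude_mV) with header row."""
    t = signal.start_offset + np.arange(signal.samples.size) / signal.fs
    pd.DataFrame({"time_s": t, "amplitude_mV": signal.samples}).to_csv(
        path, index=False)


def write_wfdb(signal: ECGSignal, record_path, gain: float = 200.0) -> None:
    """Write a single-channel format-16 WFDB record (.hea + .dat)."""
    record_path = Path(record_path)
    name = record_path.name
    adc = np.clip(np.round(signal.samples * gain), -32768, 32767).astype("<i2")
    (record_path.parent / f"{name}.dat").write_bytes(adc.tobytes())
    hea = (f"{name} 1 {signal.fs:g} {adc.size}\n"
           f"{name}.dat 16 {gain:g}(0)/mV {signal.adc_resolution} 0 "
           f"{int(adc[0]) if adc.size else 0} 0 0 ECG\n")
    (record_path.parent / f"{name}.hea").write_text(hea)


# --------------------------------------------------------- annotations ----

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def read_annotations(path, fs: float | None = None) -> list[float]:
    """Event times (seconds) from a MIT-format binary annotation file.

    Entries are 16-bit little-endian words: the top 6 bits hold the
    annotation code, the low 10 bits the sample delta from the previous
    event.  SKIP words carry a 32-bit delta; NUM/SUB/CHN and AUX payloads
    are skipped.  ``fs`` defaults to the sibling ``.hea`` header's rate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    if fs is None:
        hea = path.with_suffix(".hea")
        if not hea.exists():
            raise ValueError("fs not given and no sibling .hea header found")
        fs = _parse_header(hea)[2]
    raw = path.read_bytes()
    if len(raw) % 2:
        raise ValueError("malformed annotation stream (odd byte count)")
    times: list[float] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:
            break  # end of stream
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise ValueError("malformed SKIP annotation (truncated)")
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            val = (hi << 16) | lo
            if val >= 1 << 31:
                val -= 1 << 32
            pending_skip += val
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta % 2)
            continue
        t += delta + pending_skip
        pending_skip = 0
        times.append(t / fs)
    return sorted(times)


def write_annotations(times_s, fs: float, path, code: int = 1) -> None:
    """Write event times as a MIT-format annotation stream (code 1 = beat)."""
    path = Path(path)
    out = bytearray()
    prev = 0
    for t in sorted(times_s):
        sample = int(round(t * fs))
        delta = sample - prev
        prev = sample
        if delta >= 1 << 10:
            out += struct.pack("<H", (_SKIP << 10))
            out += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))


# -------------------------------------------------------------- alarms ----

def write_alarms_jsonl(alarms, path) -> None:
    Path(path).write_text("".join(a.to_json() + "\n" for a in alarms))


def read_alarms_jsonl(path) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    return [json.loads(ln) for ln in lines if ln.strip()]
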