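"""Personalized R-peak detection, RR analysis, alarms and HRV metrics.

The detector keeps no fixed voltage threshold.  A *reference peak* — the
largest amplitude seen so far, established over a 2 s warm-up so at least
one heartbeat contributes — adapts to each infant, and candidate local
maxima below 70 % of it are rejected.  The reference decays slightly from
block to block so it tracks amplitude drift instead of ratcheting upward
forever.

Rhythm classification works on RR intervals (seconds between consecutive
R-peaks).  Bradycardia (< 100 bpm) corresponds to RR > 0.6 s; tachycardia
(> 140 bpm) to RR < 0.43 s sustained for at least two beats.  The relative
RR measure 2*(RR_k - RR_{k-1})/(RR_k + RR_{k-1}) flags beat-to-beat
irregularity when it leaves the ±20 % band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeakTrain",
    "RRSeries",
    "AlarmEvent",
    "DetectorState",
    "detect_r_peaks",
    "rr_intervals",
    "classify_rhythm",
    "hrv_metrics",
    "BRADY_RR_THRESHOLD_S",
    "TACHY_RR_THRESHOLD_S",
]

#: RR bound equivalent to the 100 bpm bradycardia limit (60/100 s).
BRADY_RR_THRESHOLD_S = 0.6
#: RR bound equivalent to the 140 bpm tachycardia limit (60/140 s, 2 d.p.).
TACHY_RR_THRESHOLD_S = round(60.0 / 140.0, 2)

#: Per-block decay of the carried reference amplitude.
REFERENCE_DECAY = 0.99


@dataclass
class PeakTrain:
    """Detected R-peaks: sample indices, times and amplitudes."""

    indices: np.ndarray
    times: np.ndarray
    amplitudes: np.ndarray
    reference_peak: float
    warmup_seconds: float = 2.0

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class RRSeries:
    """RR intervals (s), the relative-RR series and interval end times."""

    rr: np.ndarray
    relative_rr: np.ndarray
    interval_end_times: np.ndarray

    def __len__(self) -> int:
        return int(self.rr.size)


@dataclass
class AlarmEvent:
    """A bradycardia or tachycardia event with its triggering interval(s)."""

    kind: str  # "bradycardia" | "tachycardia"
    onset_time: float
    rr_values: list[float]
    block_index: int = -1

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "onset_time_s": round(self.onset_time, 6),
                "rr_values_s": [round(v, 6) for v in self.rr_values],
                "block_index": self.block_index,
            }
        )


@dataclass
class DetectorState:
    """Carry-over between streamed blocks.

    ``tail`` holds the last two samples of the previous block so local
    maxima falling exactly on a block boundary are still seen with both
    neighbours; ``samples_seen`` is the global sample counter.
    """

    fs: float
    reference: float = 0.0
    last_peak_index: int | None = None
    samples_seen: int = 0
    tail: np.ndarray = field(default_factory=lambda: np.empty(0))


def _local_maxima(x: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus resolve to their left edge."""
    out: list[int] = []
    n = x.size
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def detect_r_peaks(signal, fs: float, peak_fraction: float = 0.7,
                   refractory: float = 0.2, warmup: float = 2.0,
                   carry_state: DetectorState | None = None,
                   invert: bool = False):
    """Detect R-peaks in one signal block; returns (PeakTrain, state).

    Pass the returned state back in as ``carry_state`` to continue across
    block boundaries: the reference amplitude, refractory clock and the
    boundary samples all carry over, so streamed detection matches a single
    pass over the concatenated record.
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal block")
    if invert:
        x = -x

    fresh = carry_state is None
    state = carry_state if carry_state is not None else DetectorState(fs=fs)
    if fresh and x.size < int(round(warmup * fs)):
        raise ValueError(
            f"first block ({x.size} samples) shorter than the {warmup} s warm-up"
        )

    block_start = state.samples_seen  # global index of x[0]
    tail = state.tail
    buf = np.concatenate([tail, x]) if tail.size else x
    offset = block_start - tail.size  # global index of buf[0]

    # reference decays once per block, then tracks the running maximum
    ref = state.reference * (REFERENCE_DECAY if not fresh else 1.0)
    warmup_end = int(round(warmup * fs))  # global sample index

    # running max over everything seen so far (cheap cumulative pass)
    run_max = np.maximum.accumulate(buf)

    idx_out, amp_out = [], []
    last = state.last_peak_index
    refr_samples = refractory * fs
    for i in _local_maxima(buf):
        g = offset + i
        if g < block_start - 1:
            continue  # already evaluated in the previous block
        cur_ref = max(ref, run_max[i])
        if g < warmup_end:
            continue
        if buf[i] < peak_fraction * cur_ref:
            continue
        if last is not None and g - last < refr_samples:
            continue
        idx_out.append(g)
        amp_out.append(buf[i])
        last = g

    state.reference = max(ref, float(run_max[-1]) if buf.size else ref)
    state.last_peak_index = last
    state.samples_seen = block_start + x.size
    state.tail = x[-2:].copy() if x.size >= 2 else buf[-2:].copy()

    indices = np.asarray(idx_out, dtype=int)
    train = PeakTrain(
        indices=indices,
        times=indices / fs,
        amplitudes=np.asarray(amp_out, dtype=float),
        reference_peak=state.reference,
        warmup_seconds=warmup,
    )
    return train, state


def rr_intervals(peaks: PeakTrain, fs: float | None = None) -> RRSeries:
    """RR intervals from successive peak times; empty if fewer than 2 peaks.

    ``relative_rr[j]`` compares interval j with interval j-1 and is defined
    from the second interval onward (NaN for the first).  Its algebraic
    range is the open interval (-2, 2).
    """
    times = np.asarray(peaks.times, dtype=float)
    if times.size < 2:
        empty = np.empty(0)
        return RRSeries(rr=empty, relative_rr=empty.copy(),
                        interval_end_times=empty.copy())
    rr = np.diff(times)
    rel = np.full(rr.size, np.nan)
    if rr.size >= 2:
        rel[1:] = 2.0 * (rr[1:] - rr[:-1]) / (rr[1:] + rr[:-1])
    return RRSeries(rr=rr, relative_rr=rel, interval_end_times=times[1:])


def classify_rhythm(rr: RRSeries, brady_threshold: float = BRADY_RR_THRESHOLD_S,
                    tachy_threshold: float = TACHY_RR_THRESHOLD_S,
                    relative_band: float = 0.20,
                    brady_two_beat: bool = False):
    """Scan an RR series for bradycardia/tachycardia; returns (alarms, flags).

    One bradycardia event is emitted per maximal run of intervals strictly
    above ``brady_threshold`` (a single long interval suffices by default;
    ``brady_two_beat=True`` requires the clinical two-beat confirmation).
    Tachycardia always requires at least two consecutive intervals strictly
    below ``tachy_threshold``.  ``flags[j]`` marks |relative_rr| above the
    irregularity band.
    """
    vals = np.asarray(rr.rr, dtype=float)
    ends = np.asarray(rr.interval_end_times, dtype=float)
    alarms: list[AlarmEvent] = []

    def runs(mask: np.ndarray):
        i = 0
        while i < mask.size:
            if mask[i]:
                j = i
                while j + 1 < mask.size and mask[j + 1]:
                    j += 1
                yield i, j
                i = j + 1
            i += 1

    for i, j in runs(vals > brady_threshold):
        if brady_two_beat and j - i + 1 < 2:
            continue
        alarms.append(AlarmEvent("bradycardia", float(ends[i]),
                                 [float(v) for v in vals[i : j + 1]]))
    for i, j in runs(vals < tachy_threshold):
        if j - i + 1 < 2:
            continue
        alarms.append(AlarmEvent("tachycardia", float(ends[i]),
                                 [float(v) for v in vals[i : j + 1]]))
    alarms.sort(key=lambda a: a.onset_time)

    rel = np.asarray(rr.relative_rr, dtype=float)
    flags = np.zeros(vals.size, dtype=bool)
    with np.errstate(invalid="ignore"):
        flags[~np.isnan(rel)] = np.abs(rel[~np.isnan(rel)]) > relative_band
    return alarms, flags


def hrv_metrics(rr: RRSeries, sdann_window: float = 5.0) -> dict:
    """RMSSD, SDNN and SDANN in milliseconds.

    RMSSD = root mean square of successive RR differences; SDNN = sample
    standard deviation of the RR intervals; SDANN = sample standard
    deviation of the per-window (default 5 s) mean RR.  A metric whose
    preconditions fail (fewer than two intervals, fewer than two windows)
    is reported as NaN — undefined, never zero.
    """
    vals = np.asarray(rr.rr, dtype=float)
    out = {"rmssd": math.nan, "sdnn": math.nan, "sdann": math.nan}
    if vals.size >= 2:
        diffs = np.diff(vals)
        out["rmssd"] = float(np.sqrt(np.mean(diffs**2)) * 1000.0)
        out["sdnn"] = float(np.std(vals, ddof=1) * 1000.0)
    ends = np.asarray(rr.interval_end_times, dtype=float)
    if vals.size >= 2 and sdann_window > 0:
        bins = np.floor(ends / sdann_window).astype(int)
        means = [float(vals[bins == b].mean()) for b in np.unique(bins)]
        if len(means) >= 2:
            out["sdann"] = float(np.std(means, ddof=1) * 1000.0)
    return out
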