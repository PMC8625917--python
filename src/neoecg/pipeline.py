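"""Block-streaming orchestration of the full monitoring chain.

The method is block-based by design: ECG arrives in fixed blocks (default
1000 samples — 4 s at 250 Hz, 2 s at 500 Hz) and each block runs through
baseline removal, denoising, peak detection, RR/alarm logic and optional
compression while the next block is being acquired.  Detector state (the
reference amplitude, refractory clock and boundary samples) carries across
blocks, so peaks and RR intervals spanning a block boundary are never
lost; input delivered in arbitrary-sized chunks is re-buffered into the
configured block size, which makes streamed and whole-record processing
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compress import CompressedBlock, compress_block
from .io import ECGSignal
from .preprocess import denoise, remove_baseline
from .rhythm import (AlarmEvent, DetectorState, PeakTrain, RRSeries,
                     detect_r_peaks, hrv_metrics, rr_intervals)
from .swt import WaveletConfig

__all__ = ["PipelineConfig", "PipelineResult", "process_stream", "process_record"]


@dataclass(frozen=True)
class PipelineConfig:
    block_size: int = 1000
    wavelet: WaveletConfig = field(default_factory=lambda: WaveletConfig(levels=5))
    peak_fraction: float = 0.7
    refractory: float = 0.2
    warmup: float = 2.0
    brady_threshold: float = 0.6
    tachy_threshold: float = 0.43
    relative_band: float = 0.20
    brady_two_beat: bool = False
    invert: bool = False
    compress: bool = False
    bits: int = 8
    input_bit_depth: int = 16
    hrv_window: float = 5.0

    def __post_init__(self) -> None:
        if self.block_size < 2**self.wavelet.levels:
            raise ValueError(
                f"block_size {self.block_size} < 2^levels "
                f"({2**self.wavelet.levels})")
        for name in ("peak_fraction", "warmup", "brady_threshold",
                     "tachy_threshold", "relative_band"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    peaks: PeakTrain
    rr: RRSeries
    alarms: list
    irregular: np.ndarray
    hrv: dict
    hrv_windows: list
    compressed: list
    report: dict


class _RhythmTracker:
    """Streaming run-length alarm logic, equivalent to classify_rhythm.

    Bradycardia: one event per maximal run of intervals strictly above the
    threshold (length >= 2 in two-beat mode).  Tachycardia: one event per
    maximal run of at least two intervals strictly below the threshold.
    Events grow in place while their run is open, so streamed output
    matches a single offline pass.
    """

    def __init__(self, config: PipelineConfig, fs: float):
        self.cfg = config
        self.fs = fs
        self.alarms: list[AlarmEvent] = []
        self._open_brady: AlarmEvent | None = None
        self._brady_pending: tuple[float, float] | None = None  # two-beat mode
        self._tachy_run: list[tuple[float, float]] = []  # (end_time, rr)
        self._open_tachy: AlarmEvent | None = None

    def _block_of(self, t: float) -> int:
        return int(t * self.fs) // self.cfg.block_size

    def push(self, rr: float, end_time: float) -> None:
        cfg = self.cfg
        # bradycardia run
        if rr > cfg.brady_threshold:
            if self._open_brady is not None:
                self._open_brady.rr_values.append(rr)
            elif cfg.brady_two_beat and self._brady_pending is None:
                self._brady_pending = (end_time, rr)
            else:
                if cfg.brady_two_beat:
                    t0, rr0 = self._brady_pending
                    ev = AlarmEvent("bradycardia", t0, [rr0, rr],
                                    self._block_of(t0))
                    self._brady_pending = None
                else:
                    ev = AlarmEvent("bradycardia", end_time, [rr],
                                    self._block_of(end_time))
                self.alarms.append(ev)
                self._open_brady = ev
        else:
            self._open_brady = None
            self._brady_pending = None
        # tachycardia run (needs >= 2 consecutive short intervals)
        if rr < cfg.tachy_threshold:
            if self._open_tachy is not None:
                self._open_tachy.rr_values.append(rr)
            else:
                self._tachy_run.append((end_time, rr))
                if len(self._tachy_run) == 2:
                    t0, rr0 = self._tachy_run[0]
                    ev = AlarmEvent("tachycardia", t0,
                                    [rr0, rr], self._block_of(t0))
                    self.alarms.append(ev)
                    self._open_tachy = ev
                    self._tachy_run = []
        else:
            self._open_tachy = None
            self._tachy_run = []

    def finish(self) -> list[AlarmEvent]:
        self.alarms.sort(key=lambda a: a.onset_time)
        return self.alarms


def _iter_blocks(source, block_size: int):
    """Re-buffer arbitrary chunks into fixed-size blocks (last may be short)."""
    buf = np.empty(0)
    for chunk in source:
        chunk = np.asarray(chunk, dtype=float).ravel()
        buf = np.concatenate([buf, chunk]) if buf.size else chunk
        while buf.size >= block_size:
            yield buf[:block_size]
            buf = buf[block_size:]
    if buf.size:
        yield buf


def _preprocess_block(block: np.ndarray, config: PipelineConfig):
    """Baseline removal + denoising, degrading gracefully on short tails."""
    levels = config.wavelet.levels
    if block.size < 2:
        return block, 0
    max_levels = int(np.floor(np.log2(block.size)))
    used = min(levels, max_levels)
    wc = (config.wavelet if used == levels
          else WaveletConfig(config.wavelet.wavelet_name, used,
                             config.wavelet.boundary_mode))
    corrected, _ = remove_baseline(block, config=wc)
    return denoise(corrected, wc), used


def process_stream(source, fs: float, config: PipelineConfig | None = None,
                   log=None) -> PipelineResult:
    """Run the full chain over a block stream; see module docstring.

    ``source`` is an ECGSignal or any iterable of 1-D sample chunks; ``fs``
    is ignored (taken from the record) when an ECGSignal is passed.
    """
    if config is None:
        config = PipelineConfig()
    if isinstance(source, ECGSignal):
        fs = source.fs
        chunks = [source.samples]
    else:
        chunks = source
    if fs is None or fs <= 0:
        raise ValueError("a positive sampling rate is required")

    state = DetectorState(fs=fs)
    tracker = _RhythmTracker(config, fs)
    peak_idx: list[int] = []
    peak_amp: list[float] = []
    compressed: list[CompressedBlock] = []
    short_blocks = 0
    n_samples = 0
    n_blocks = 0
    prev_peak_t: float | None = None

    for block in _iter_blocks(chunks, config.block_size):
        processed, used_levels = _preprocess_block(block, config)
        if used_levels < config.wavelet.levels:
            short_blocks += 1
            if log is not None:
                log.warning("block %d: %d samples, reduced to %d levels",
                            n_blocks, block.size, used_levels)
        train, state = detect_r_peaks(
            processed, fs, peak_fraction=config.peak_fraction,
            refractory=config.refractory, warmup=config.warmup,
            carry_state=state, invert=config.invert)
        for g, a in zip(train.indices, train.amplitudes):
            t = int(g) / fs
            if prev_peak_t is not None:
                tracker.push(t - prev_peak_t, t)
            prev_peak_t = t
            peak_idx.append(int(g))
            peak_amp.append(float(a))
        if config.compress and block.size >= 2**config.wavelet.levels:
            compressed.append(compress_block(
                block, config.wavelet, bits=config.bits,
                input_bit_depth=config.input_bit_depth))
        n_samples += block.size
        n_blocks += 1

    indices = np.asarray(peak_idx, dtype=int)
    peaks = PeakTrain(indices=indices, times=indices / fs,
                      amplitudes=np.asarray(peak_amp),
                      reference_peak=state.reference,
                      warmup_seconds=config.warmup)
    rr = rr_intervals(peaks, fs)
    alarms = tracker.finish()
    rel = np.asarray(rr.relative_rr)
    irregular = np.zeros(rr.rr.size, dtype=bool)
    if rel.size:
        ok = ~np.isnan(rel)
        irregular[ok] = np.abs(rel[ok]) > config.relative_band

    hrv = hrv_metrics(rr, sdann_window=config.hrv_window)
    hrv_windows = _windowed_hrv(rr, config.hrv_window)

    report = {
        "fs": fs,
        "n_samples": n_samples,
        "n_blocks": n_blocks,
        "short_blocks": short_blocks,
        "n_peaks": len(peaks),
        "n_alarms": len(alarms),
        "mean_cr": (float(np.mean([b.cr for b in compressed]))
                    if compressed else None),
    }
    return PipelineResult(peaks, rr, alarms, irregular, hrv, hrv_windows,
                          compressed, report)


def _windowed_hrv(rr: RRSeries, window_s: float) -> list[dict]:
    """Per-window RMSSD/SDNN (e.g. every 2 s or 5 s) for trend monitoring."""
    out = []
    if rr.rr.size == 0 or window_s <= 0:
        return out
    bins = np.floor(rr.interval_end_times / window_s).astype(int)
    for b in np.unique(bins):
        sel = bins == b
        sub = RRSeries(rr=rr.rr[sel], relative_rr=rr.relative_rr[sel],
                       interval_end_times=rr.interval_end_times[sel])
        m = hrv_metrics(sub, sdann_window=window_s)
        out.append({"window_start_s": float(b * window_s),
                    "n_intervals": int(sel.sum()),
                    "rmssd_ms": m["rmssd"], "sdnn_ms": m["sdnn"]})
    return out


def process_record(signal: ECGSignal, config: PipelineConfig | None = None,
                   log=None) -> PipelineResult:
    """Whole-record processing (internally identical to streaming)."""
    return process_stream(signal, signal.fs, config, log=log)
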