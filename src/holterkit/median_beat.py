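"""Per-segment median beats, the heart-rate-matched baseline library, and
ST / T-wave deviation measurement.

The deviation of a 10-s segment is measured between its median beat and the
patient's own baseline median beat for the matching heart-rate bin:

* ST deviation: mean amplitude over the ST window (J+40 to J+80 ms, J = QRS
  offset) minus the same quantity of the baseline beat, after referencing
  both beats to their PQ-segment isoelectric level;
* T-wave deviations: change of the minimum / maximum amplitude over the T
  window (QRS offset + 80 ms to T offset).

The baseline library is built from the whole recording, binned in 5-bpm
heart-rate bins spanning 40-140 bpm; bins need at least 10 contributing
segments.  A segment is never compared against a bin more than 10 bpm away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .containers import (BeatAnnotation, DeviationSeries, EcgRecording,
                         SEGMENT_SECONDS)
from .leads import LEADS


class InsufficientBaselineError(ValueError):
    """No heart-rate bin accumulated enough segments for a baseline."""


@dataclass
class MedianBeat:
    """Per-lead sample-wise median beat of one 10-s segment, aligned on the
    QRS onset (t = 0)."""

    segment_start: float
    t_ms: np.ndarray              # sample grid, ms relative to QRS onset
    waveform: np.ndarray          # (n_samples, 12) mV
    hr_bpm: float
    beat_count: int
    qrs_ms: float                 # inherited segment median intervals
    qt_ms: float


@dataclass
class BaselineBeat:
    waveform: np.ndarray
    n_segments: int
    qrs_ms: float
    qt_ms: float


@dataclass
class BaselineLibrary:
    """Per-patient mapping: heart-rate bin id -> baseline median beat."""

    t_ms: np.ndarray
    bins: dict[int, BaselineBeat] = field(default_factory=dict)
    bin_width: float = 5.0
    bin_min: float = 40.0

    def bin_of(self, hr_bpm: float) -> int:
        """Bins are centered on multiples of the bin width (the 60-bpm bin
        spans 57.5-62.5 bpm)."""
        return int(np.clip(np.round((hr_bpm - self.bin_min) / self.bin_width),
                           0, (140.0 - self.bin_min) / self.bin_width))

    def bin_center(self, b: int) -> float:
        return self.bin_min + b * self.bin_width

    def match(self, hr_bpm: float, max_dist_bpm: float = 10.0,
              ) -> Optional[int]:
        """The segment's own bin if populated, else the nearest populated bin
        within the allowed heart-rate distance."""
        if not self.bins or not np.isfinite(hr_bpm):
            return None
        b = self.bin_of(hr_bpm)
        if b in self.bins:
            return b
        best, best_d = None, np.inf
        for k in self.bins:
            d = abs(self.bin_center(k) - hr_bpm)
            if d < best_d:
                best, best_d = k, d
        return best if best_d <= max_dist_bpm else None


def _window_grid(fs: float, cfg: PipelineConfig) -> np.ndarray:
    lo, hi = cfg.beat_window_ms
    step = 1000.0 / fs
    return np.arange(int(np.round(lo / step)),
                     int(np.round(hi / step)) + 1) * step


def compute_median_beat(rec: EcgRecording,
                        segment_beats: Sequence[BeatAnnotation],
                        segment_start: float,
                        config: PipelineConfig = DEFAULT_CONFIG,
                        ) -> Optional[MedianBeat]:
    """Sample-wise median across QRS-onset-aligned sinus beats of one
    segment; ``None`` with fewer than the minimum beats."""
    fs = rec.fs
    beats = [b for b in segment_beats
             if b.classification == "sinus" and b.qrs_onset is not None]
    if len(beats) < config.min_beats_per_window:
        return None
    t_ms = _window_grid(fs, config)
    rel = np.round(t_ms * fs / 1000.0).astype(int)
    stacks = []
    for b in beats:
        on = int(round(b.qrs_onset * fs))
        idx = on + rel
        if idx[0] < 0 or idx[-1] >= rec.n_samples:
            continue
        stacks.append(rec.signal[idx, :])
    if len(stacks) < config.min_beats_per_window:
        return None
    med = np.median(np.stack(stacks), axis=0)

    def _med(vals):
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        return float(np.median(vals)) if vals else np.nan

    rr = _med([b.rr_ms for b in beats])
    hr = 60000.0 / rr if np.isfinite(rr) and rr > 0 else np.nan
    return MedianBeat(segment_start=segment_start, t_ms=t_ms, waveform=med,
                      hr_bpm=hr, beat_count=len(stacks),
                      qrs_ms=_med([b.qrs_ms for b in beats]),
                      qt_ms=_med([b.qt_ms for b in beats]))


def median_beats_by_segment(rec: EcgRecording,
                            beats: Sequence[BeatAnnotation],
                            usable: np.ndarray,
                            config: PipelineConfig = DEFAULT_CONFIG,
                            ) -> list[Optional[MedianBeat]]:
    """One median beat per 10-s segment (None where unusable/undersupported)."""
    n_seg = int(rec.duration_s // SEGMENT_SECONDS)
    by_seg: list[list[BeatAnnotation]] = [[] for _ in range(n_seg)]
    for b in beats:
        wi = int(b.r_time // SEGMENT_SECONDS)
        if 0 <= wi < n_seg:
            by_seg[wi].append(b)
    out: list[Optional[MedianBeat]] = []
    for wi in range(n_seg):
        if wi < len(usable) and usable[wi]:
            out.append(compute_median_beat(rec, by_seg[wi],
                                           wi * SEGMENT_SECONDS, config))
        else:
            out.append(None)
    return out


def build_baseline_library(median_beats: Sequence[Optional[MedianBeat]],
                           config: PipelineConfig = DEFAULT_CONFIG,
                           ) -> BaselineLibrary:
    """Heart-rate-binned baselines from the patient's full recording.

    Raises :class:`InsufficientBaselineError` when no bin reaches the minimum
    segment support.
    """
    lib = BaselineLibrary(t_ms=np.empty(0), bin_width=config.hr_bin_width_bpm,
                          bin_min=config.hr_bin_min_bpm)
    groups: dict[int, list[MedianBeat]] = {}
    for mb in median_beats:
        if mb is None or not np.isfinite(mb.hr_bpm):
            continue
        if not (config.hr_bin_min_bpm <= mb.hr_bpm < config.hr_bin_max_bpm):
            continue
        groups.setdefault(lib.bin_of(mb.hr_bpm), []).append(mb)
    for b, mbs in sorted(groups.items()):
        if len(mbs) < config.baseline_min_segments:
            continue
        wave = np.median(np.stack([m.waveform for m in mbs]), axis=0)
        lib.bins[b] = BaselineBeat(
            waveform=wave, n_segments=len(mbs),
            qrs_ms=float(np.nanmedian([m.qrs_ms for m in mbs])),
            qt_ms=float(np.nanmedian([m.qt_ms for m in mbs])))
        if lib.t_ms.size == 0:
            lib.t_ms = mbs[0].t_ms
    if not lib.bins:
        raise InsufficientBaselineError(
            "insufficient baseline: no heart-rate bin reached "
            f"{config.baseline_min_segments} segments")
    return lib


# ---------------------------------------------------------------------------
# deviation measurement
# ---------------------------------------------------------------------------

def _iso_level(t_ms: np.ndarray, wave: np.ndarray,
               cfg: PipelineConfig) -> np.ndarray:
    lo, hi = cfg.iso_window_ms
    m = (t_ms >= lo) & (t_ms <= hi)
    return wave[m].mean(axis=0)


def _st_mean(t_ms: np.ndarray, wave: np.ndarray, qrs_ms: float,
             cfg: PipelineConfig) -> np.ndarray:
    lo, hi = cfg.st_window_ms
    m = (t_ms >= qrs_ms + lo) & (t_ms <= qrs_ms + hi)
    if not m.any():
        return np.full(wave.shape[1], np.nan)
    return wave[m].mean(axis=0)


def _t_extrema(t_ms: np.ndarray, wave: np.ndarray, qrs_ms: float,
               qt_ms: float, cfg: PipelineConfig,
               ) -> tuple[np.ndarray, np.ndarray]:
    m = (t_ms >= qrs_ms + cfg.t_window_start_ms) & (t_ms <= qt_ms)
    if not m.any() or not np.isfinite(qt_ms):
        nan = np.full(wave.shape[1], np.nan)
        return nan, nan
    w = wave[m]
    return w.min(axis=0), w.max(axis=0)


def st_deviation(mb: MedianBeat, lib: BaselineLibrary,
                 config: PipelineConfig = DEFAULT_CONFIG,
                 ) -> tuple[Optional[np.ndarray], int]:
    """Per-lead ST deviation (mV) of a segment median beat against its
    heart-rate-matched baseline; (None, -1) when no bin matches."""
    b = lib.match(mb.hr_bpm, config.hr_match_max_bpm)
    if b is None:
        return None, -1
    base = lib.bins[b]
    seg = (_st_mean(mb.t_ms, mb.waveform, mb.qrs_ms, config)
           - _iso_level(mb.t_ms, mb.waveform, config))
    ref = (_st_mean(lib.t_ms, base.waveform, base.qrs_ms, config)
           - _iso_level(lib.t_ms, base.waveform, config))
    return seg - ref, b


def t_wave_deviation(mb: MedianBeat, lib: BaselineLibrary,
                     config: PipelineConfig = DEFAULT_CONFIG,
                     ) -> tuple[Optional[np.ndarray], Optional[np.ndarray], int]:
    """Per-lead (min-T deviation, max-T deviation) in mV."""
    b = lib.match(mb.hr_bpm, config.hr_match_max_bpm)
    if b is None:
        return None, None, -1
    base = lib.bins[b]
    iso_s = _iso_level(mb.t_ms, mb.waveform, config)
    iso_b = _iso_level(lib.t_ms, base.waveform, config)
    mn_s, mx_s = _t_extrema(mb.t_ms, mb.waveform, mb.qrs_ms, mb.qt_ms, config)
    mn_b, mx_b = _t_extrema(lib.t_ms, base.waveform, base.qrs_ms,
                            base.qt_ms, config)
    return (mn_s - iso_s) - (mn_b - iso_b), (mx_s - iso_s) - (mx_b - iso_b), b


def deviation_series(median_beats: Sequence[Optional[MedianBeat]],
                     lib: BaselineLibrary,
                     usable: np.ndarray,
                     config: PipelineConfig = DEFAULT_CONFIG,
                     start_time=None) -> DeviationSeries:
    """Assemble the per-segment, per-lead DeviationSeries for one patient."""
    n = len(median_beats)
    st = np.full((n, len(LEADS)), np.nan)
    tmin = np.full((n, len(LEADS)), np.nan)
    tmax = np.full((n, len(LEADS)), np.nan)
    bbin = np.full(n, -1, int)
    seg_start = np.array([i * SEGMENT_SECONDS for i in range(n)])
    us = np.zeros(n, bool)
    us[:min(len(usable), n)] = np.asarray(usable, bool)[:n]
    for i, mb in enumerate(median_beats):
        if mb is None or not us[i]:
            continue
        dev, b = st_deviation(mb, lib, config)
        if dev is None:
            continue
        mn, mx, _ = t_wave_deviation(mb, lib, config)
        st[i] = dev
        if mn is not None:
            tmin[i] = mn
            tmax[i] = mx
        bbin[i] = b
    kwargs = {} if start_time is None else {"start_time": start_time}
    return DeviationSeries(segment_start=seg_start, st=st, tmin=tmin,
                           tmax=tmax, usable=us, baseline_bin=bbin, **kwargs)
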