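"""Shared in-memory containers for waveforms, beat annotations and the
per-10-s series that the downstream analyses consume.

Times are seconds from the start of the recording; ``EcgRecording.start_time``
anchors them to the local wall clock (naive datetimes, interpreted in the
recording's local time zone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .leads import LEADS, normalize_lead

SEGMENT_SECONDS = 10.0  # the analysis grid: one segment = 10 s


@dataclass
class EcgRecording:
    """Continuous multi-lead ECG waveform.

    signal is shaped (n_samples, n_leads) in mV; ``gaps`` are half-open
    ``(start_s, end_s)`` intervals of zero-filled, unusable signal.
    """

    signal: np.ndarray
    fs: float
    leads: tuple[str, ...] = LEADS
    start_time: datetime = datetime(2024, 1, 1, 10, 0, 0)
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.leads):
            raise ValueError("signal must be (n_samples, n_leads)")
        self.leads = tuple(normalize_lead(l) for l in self.leads)
        dur = self.duration_s
        prev_end = -1.0
        for a, b in sorted(self.gaps):
            if not (0.0 <= a < b <= dur + 1e-9):
                raise ValueError(f"gap ({a}, {b}) outside record span")
            if a < prev_end:
                raise ValueError("gap intervals overlap")
            prev_end = b

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, self.leads.index(normalize_lead(name))]

    def time_of(self, seconds: float) -> datetime:
        return self.start_time + timedelta(seconds=float(seconds))

    def in_gap(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.gaps)


@dataclass
class BeatAnnotation:
    """One detected heartbeat with its fiducials and per-beat intervals.

    All times are seconds from recording start; intervals are milliseconds.
    Fiducials that could not be resolved are ``None``.
    """

    r_time: float
    classification: str = "sinus"  # sinus | non_sinus | artifact
    p_onset: Optional[float] = None
    p_offset: Optional[float] = None
    qrs_onset: Optional[float] = None
    qrs_offset: Optional[float] = None
    t_offset: Optional[float] = None
    pq_ms: Optional[float] = None
    qrs_ms: Optional[float] = None
    qt_ms: Optional[float] = None
    rr_ms: Optional[float] = None  # to previous sinus beat

    def fiducials_ordered(self) -> bool:
        seq = [t for t in (self.p_onset, self.p_offset, self.qrs_onset,
                           self.qrs_offset, self.t_offset) if t is not None]
        return all(a <= b for a, b in zip(seq, seq[1:]))


@dataclass
class IntervalSeries:
    """Per-10-s medians of heart rate and conduction times over sinus beats."""

    window_start: np.ndarray      # seconds from recording start
    hr_bpm: np.ndarray
    pq_ms: np.ndarray
    qrs_ms: np.ndarray
    qt_ms: np.ndarray
    beat_count: np.ndarray
    usable: np.ndarray            # bool
    start_time: datetime = datetime(2024, 1, 1, 10, 0, 0)

    def __len__(self) -> int:
        return len(self.window_start)

    def clock_hours(self) -> np.ndarray:
        """Local wall-clock hour-of-day (fractional) of each window start."""
        base = (self.start_time.hour * 3600 + self.start_time.minute * 60
                + self.start_time.second)
        return ((base + self.window_start) % 86400.0) / 3600.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start": self.window_start,
            "hr_bpm": self.hr_bpm,
            "pq_ms": self.pq_ms,
            "qrs_ms": self.qrs_ms,
            "qt_ms": self.qt_ms,
            "beat_count": self.beat_count,
            "usable": self.usable,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   start_time: datetime = datetime(2024, 1, 1, 10, 0, 0),
                   ) -> "IntervalSeries":
        return cls(
            window_start=df["window_start"].to_numpy(float),
            hr_bpm=df["hr_bpm"].to_numpy(float),
            pq_ms=df["pq_ms"].to_numpy(float),
            qrs_ms=df["qrs_ms"].to_numpy(float),
            qt_ms=df["qt_ms"].to_numpy(float),
            beat_count=df["beat_count"].to_numpy(int),
            usable=df["usable"].to_numpy(bool),
            start_time=start_time,
        )


@dataclass
class SdnnSeries:
    """SDNN (ms) of sinus-to-sinus intervals per 5-min window."""

    window_start: np.ndarray
    sdnn_ms: np.ndarray    # NaN when NN count below the minimum
    nn_count: np.ndarray
    start_time: datetime = datetime(2024, 1, 1, 10, 0, 0)

    def __len__(self) -> int:
        return len(self.window_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start": self.window_start,
            "sdnn_ms": self.sdnn_ms,
            "nn_count": self.nn_count,
        })


@dataclass
class DeviationSeries:
    """Per-10-s-segment, per-lead ST and T-wave deviations from the
    heart-rate-matched baseline median beat (mV, signed).

    Arrays are shaped (n_segments, 12); NaN marks segments without a usable
    median beat or without a matched baseline bin.
    """

    segment_start: np.ndarray   # seconds from recording start
    st: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    usable: np.ndarray          # bool per segment
    baseline_bin: np.ndarray    # int bin id, -1 when unmatched
    leads: tuple[str, ...] = LEADS
    start_time: datetime = datetime(2024, 1, 1, 10, 0, 0)

    def __len__(self) -> int:
        return len(self.segment_start)

    def measure(self, parameter: str) -> np.ndarray:
        """Return the (n_segments, 12) array behind an ischemia parameter."""
        if parameter in ("st_deviation", "st_elevation", "st_depression"):
            return self.st
        if parameter == "tmin_deviation":
            return self.tmin
        if parameter == "tmax_deviation":
            return self.tmax
        raise ValueError(f"unknown ischemia parameter: {parameter!r}")

    def to_frame(self) -> pd.DataFrame:
        n = len(self)
        recs = []
        for j, lead in enumerate(self.leads):
            recs.append(pd.DataFrame({
                "segment_start": self.segment_start,
                "lead": lead,
                "st_dev_mv": self.st[:, j],
                "tmin_dev_mv": self.tmin[:, j],
                "tmax_dev_mv": self.tmax[:, j],
                "baseline_bin": self.baseline_bin,
                "usable": self.usable,
            }))
        return pd.concat(recs, ignore_index=True).sort_values(
            ["segment_start", "lead"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   start_time: datetime = datetime(2024, 1, 1, 10, 0, 0),
                   ) -> "DeviationSeries":
        seg = np.sort(df["segment_start"].unique())
        idx = {s: i for i, s in enumerate(seg)}
        n = len(seg)
        st = np.full((n, len(LEADS)), np.nan)
        tmin = np.full((n, len(LEADS)), np.nan)
        tmax = np.full((n, len(LEADS)), np.nan)
        usable = np.zeros(n, bool)
        bbin = np.full(n, -1, int)
        lead_ix = {l: j for j, l in enumerate(LEADS)}
        ii = df["segment_start"].map(idx).to_numpy()
        jj = df["lead"].map(lead_ix).to_numpy()
        st[ii, jj] = df["st_dev_mv"].to_numpy(float)
        tmin[ii, jj] = df["tmin_dev_mv"].to_numpy(float)
        tmax[ii, jj] = df["tmax_dev_mv"].to_numpy(float)
        usable[ii] = df["usable"].to_numpy(bool)
        bbin[ii] = df["baseline_bin"].to_numpy(int)
        return cls(segment_start=seg, st=st, tmin=tmin, tmax=tmax,
                   usable=usable, baseline_bin=bbin, start_time=start_time)


ISCHEMIA_PARAMETERS = (
    "st_deviation", "st_elevation", "st_depression",
    "tmin_deviation", "tmax_deviation",
)

SYMPTOM_TYPES = ("chest_pain", "dyspnea", "fatigue", "other")
ACUTE_SYMPTOM_TYPES = ("chest_pain", "dyspnea")
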