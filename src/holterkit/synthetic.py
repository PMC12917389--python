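"""Synthetic multi-day 12-lead Holter cohort generator.

The generator emulates what the analysis pipeline assumes about ambulatory
recordings from patients with suspected coronary vasomotor dysfunction:

* circadian heart-rate, PQ and QT rhythms (cosine models; QT tied to RR by a
  configurable Bazett relation),
* transient multi-lead ST-depression / T-amplitude episodes with amplitudes
  in the 0.02-0.10 mV range,
* symptom events partially concurrent with episodes, reported incompletely
  and inconsistently through an event diary and a device button,
* noise, artifact bursts and recording gaps (shower/battery disconnections),
* a two-group cohort in which ischemia-prone patients are more frequent in
  the CAS group.

Two tiers share the same patient model:

``generate_recording``
    renders the actual 200 Hz waveform (used at minutes-to-hours scale to
    exercise beat detection, delineation and median-beat deviation
    measurement), and
``generate_patient_series``
    emits the per-10-s interval/deviation series directly (used for day- and
    cohort-scale studies where waveform synthesis would be pointless).

Everything is driven by explicit seeds; identical seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import (ACUTE_SYMPTOM_TYPES, DeviationSeries, EcgRecording,
                         IntervalSeries, SdnnSeries, SEGMENT_SECONDS,
                         SYMPTOM_TYPES)
from .leads import LEADS, LEAD_INDEX
from .templates import MorphologyTemplate

DEFAULT_START = datetime(2024, 1, 1, 10, 0, 0)


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class EpisodeSpec:
    """One injected transient ischemia-like episode."""

    kind: str                  # "st_offset" or "t_scale"
    amplitude_mv: float        # signed; for t_scale: additive change of T amp
    leads: tuple[str, ...]
    start_s: float
    duration_s: float
    ramp_s: float = 10.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("episode duration must be positive")
        if not self.leads:
            raise ValueError("episode lead set must be non-empty")
        bad = [l for l in self.leads if l not in LEAD_INDEX]
        if bad:
            raise ValueError(f"invalid lead name(s): {bad}")
        if self.kind not in ("st_offset", "t_scale"):
            raise ValueError(f"unknown episode kind: {self.kind!r}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def envelope(self, t: float) -> float:
        """Temporal on/off ramp factor in [0, 1] at time t."""
        if t <= self.start_s or t >= self.end_s:
            return 0.0
        r = max(self.ramp_s, 1e-9)
        return float(min(1.0, (t - self.start_s) / r, (self.end_s - t) / r))


@dataclass
class PatientSpec:
    """All data-generating parameters for one simulated patient."""

    group: str = "CAS"                      # "CAS" | "no_CAS"
    duration_days: float = 3.0
    start_time: datetime = DEFAULT_START
    seed: int = 0
    allow_any_duration: bool = False        # wear protocol is 2-7 days

    # circadian heart rate: mesor + amplitude * cos(2*pi*(h - acrophase)/24)
    hr_mesor_bpm: float = 70.0
    hr_amplitude_bpm: float = 10.0
    hr_acrophase_h: float = 15.0
    rr_jitter_ms: float = 20.0

    # conduction intervals
    pq_base_ms: float = 160.0
    pq_nocturnal_ms: float = 14.0           # added at the 03:00 nadir
    qrs_ms: float = 92.0
    qtc_base_ms: float = 440.0              # QT = qtc * sqrt(RR_s) (Bazett)
    qt_nocturnal_ms: float = 0.0

    # episodes: explicit list wins over the random episode model
    fixed_episodes: tuple = ()
    ischemia_prone_prob: float = 0.0        # P(this patient has episodes)
    episode_rate_per_day: float = 4.0
    episode_kind: str = "st_offset"
    episode_amp_mean_mv: float = -0.05      # depression by default
    episode_amp_sd_mv: float = 0.02
    episode_duration_median_s: float = 150.0
    episode_duration_sdlog: float = 0.4
    episode_ramp_s: float = 10.0
    episode_lead_groups: tuple[tuple[str, ...], ...] = (
        ("V4", "V5"), ("V5", "V6"), ("V4", "V5", "V6"),
        ("II", "III", "aVF"), ("V2", "V3"), ("I", "aVL"),
    )

    # symptoms
    background_symptom_rate_per_day: float = 4.8
    episode_symptom_prob: float = 0.0
    diary_prob: float = 0.286
    button_prob: float = 0.211
    button_jitter_min: float = 2.0

    # noise / artifacts / gaps
    noise_rms_mv: float = 0.01
    st_noise_sd_mv: float = 0.008           # series-tier per-segment ST noise
    artifact_fraction: float = 0.18
    artifact_burst_mean_s: float = 30.0
    artifact_amp_mv: float = 1.5
    daily_gap_minutes: float = 20.0
    gap_hour: float = 9.0
    ectopic_prob: float = 0.0

    # between-patient variation applied by generate_cohort
    bp_sd: dict = field(default_factory=lambda: {
        "hr_mesor_bpm": 6.0, "pq_base_ms": 18.0, "qtc_base_ms": 20.0})

    def __post_init__(self) -> None:
        for name in ("episode_rate_per_day", "background_symptom_rate_per_day",
                     "noise_rms_mv", "st_noise_sd_mv", "rr_jitter_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ischemia_prone_prob", "episode_symptom_prob",
                     "diary_prob", "button_prob", "artifact_fraction",
                     "ectopic_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if not self.allow_any_duration and not 2.0 <= self.duration_days <= 7.0:
            raise ValueError("recording duration must be 2-7 days "
                             "(set allow_any_duration=True to override)")

    # --- circadian models -------------------------------------------------

    def clock_hours(self, t_s: np.ndarray | float) -> np.ndarray:
        base = (self.start_time.hour * 3600 + self.start_time.minute * 60
                + self.start_time.second)
        return ((base + np.asarray(t_s, dtype=float)) % 86400.0) / 3600.0

    def hr_at(self, t_s):
        h = self.clock_hours(t_s)
        return (self.hr_mesor_bpm + self.hr_amplitude_bpm
                * np.cos(2 * np.pi * (h - self.hr_acrophase_h) / 24.0))

    def night_weight(self, t_s):
        """1 at the 03:00 nocturnal peak, 0 at 15:00."""
        h = self.clock_hours(t_s)
        return 0.5 * (1.0 + np.cos(2 * np.pi * (h - 3.0) / 24.0))

    def pq_at(self, t_s):
        return self.pq_base_ms + self.pq_nocturnal_ms * self.night_weight(t_s)

    def qt_from_rr(self, rr_ms, t_s):
        rr_s = np.asarray(rr_ms, dtype=float) / 1000.0
        return (self.qtc_base_ms * np.sqrt(rr_s)
                + self.qt_nocturnal_ms * self.night_weight(t_s))

    @property
    def duration_s(self) -> float:
        return self.duration_days * 86400.0

    def gap_intervals(self) -> list[tuple[float, float]]:
        """Daily disconnection gaps (e.g. showers), clipped to the span."""
        if self.daily_gap_minutes <= 0:
            return []
        gaps = []
        start_clock = (self.start_time.hour * 3600
                       + self.start_time.minute * 60 + self.start_time.second)
        first = (self.gap_hour * 3600.0 - start_clock) % 86400.0
        t = first
        while t < self.duration_s:
            a, b = t, min(t + self.daily_gap_minutes * 60.0, self.duration_s)
            if b > a:
                gaps.append((a, b))
            t += 86400.0
        return gaps


@dataclass
class SymptomEvent:
    time_s: float
    type: str
    from_episode: bool = False


@dataclass
class GroundTruth:
    """Everything injected into one synthetic recording."""

    spec: PatientSpec
    episodes: list[EpisodeSpec] = field(default_factory=list)
    symptoms: list[SymptomEvent] = field(default_factory=list)
    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    beat_is_ectopic: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    beat_pq_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    beat_qt_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    gaps: list[tuple[float, float]] = field(default_factory=list)
    ischemia_prone: bool = False

    def true_burden_s(self, cutoff_mv: float, min_duration_s: float = 30.0,
                      ) -> float:
        """Total injected episode time at or above an ST cutoff (plateau
        amplitude; ramps ignored), counting only episodes long enough and
        with >= 2 leads."""
        total = 0.0
        for ep in self.episodes:
            if (abs(ep.amplitude_mv) >= cutoff_mv
                    and ep.duration_s >= min_duration_s
                    and len(ep.leads) >= 2):
                total += ep.duration_s
        return total

    def to_dict(self) -> dict:
        return {
            "group": self.spec.group,
            "seed": self.spec.seed,
            "ischemia_prone": bool(self.ischemia_prone),
            "episodes": [{
                "kind": e.kind, "amplitude_mv": e.amplitude_mv,
                "leads": list(e.leads), "start_s": e.start_s,
                "duration_s": e.duration_s, "ramp_s": e.ramp_s,
            } for e in self.episodes],
            "symptoms": [{
                "time_s": s.time_s, "type": s.type,
                "from_episode": s.from_episode,
            } for s in self.symptoms],
            "gaps": [list(g) for g in self.gaps],
            "artifact_intervals": [list(a) for a in self.artifact_intervals],
        }


# ---------------------------------------------------------------------------
# episode / artifact scheduling (shared by both tiers)
# ---------------------------------------------------------------------------

def _draw_episodes(spec: PatientSpec, rng: np.random.Generator,
                   ) -> tuple[bool, list[EpisodeSpec]]:
    if spec.fixed_episodes:
        return True, sorted(spec.fixed_episodes, key=lambda e: e.start_s)
    prone = bool(rng.random() < spec.ischemia_prone_prob)
    episodes: list[EpisodeSpec] = []
    if prone and spec.episode_rate_per_day > 0:
        n = rng.poisson(spec.episode_rate_per_day * spec.duration_days)
        for _ in range(n):
            dur = float(np.exp(rng.normal(
                math.log(spec.episode_duration_median_s),
                spec.episode_duration_sdlog)))
            dur = min(dur, spec.duration_s / 2.0)
            start = float(rng.uniform(60.0, max(61.0, spec.duration_s - dur - 60.0)))
            amp = float(rng.normal(spec.episode_amp_mean_mv,
                                   spec.episode_amp_sd_mv))
            if spec.episode_amp_mean_mv < 0:
                amp = -abs(amp)
            elif spec.episode_amp_mean_mv > 0:
                amp = abs(amp)
            leads = tuple(spec.episode_lead_groups[
                rng.integers(len(spec.episode_lead_groups))])
            episodes.append(EpisodeSpec(
                kind=spec.episode_kind, amplitude_mv=amp, leads=leads,
                start_s=start, duration_s=dur, ramp_s=spec.episode_ramp_s))
    episodes.sort(key=lambda e: e.start_s)
    return prone, episodes


def _draw_artifacts(spec: PatientSpec, rng: np.random.Generator,
                    ) -> list[tuple[float, float]]:
    """Artifact bursts aligned to the 10-s analysis grid, non-overlapping,
    covering ``artifact_fraction`` of the recording (so the unusable fraction
    matches the configured target)."""
    if spec.artifact_fraction <= 0:
        return []
    n_win = int(spec.duration_s // SEGMENT_SECONDS)
    target = int(round(spec.artifact_fraction * n_win))
    taken = np.zeros(n_win, bool)
    covered = 0
    out = []
    attempts = 0
    while covered < target and attempts < 20 * max(target, 1):
        attempts += 1
        k = max(1, int(round(rng.exponential(spec.artifact_burst_mean_s)
                             / SEGMENT_SECONDS)))
        k = min(k, max(target - covered, 1), 60)
        w0 = int(rng.integers(0, max(n_win - k, 1)))
        if taken[w0:w0 + k].any():
            continue
        taken[w0:w0 + k] = True
        covered += k
        out.append((w0 * SEGMENT_SECONDS, (w0 + k) * SEGMENT_SECONDS))
    out.sort()
    return out


def _interval_overlap_fraction(starts: np.ndarray, width: float,
                               intervals: list[tuple[float, float]],
                               ) -> np.ndarray:
    """Fraction of each [start, start+width) window covered by intervals."""
    starts = np.asarray(starts, float)
    if not intervals:
        return np.zeros(starts.size)
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    a = np.array([m[0] for m in merged])
    b = np.array([m[1] for m in merged])
    cum = np.concatenate([[0.0], np.cumsum(b - a)])

    def covered_upto(t: np.ndarray) -> np.ndarray:
        i = np.searchsorted(a, t, side="right") - 1
        inside = np.clip(t - a[np.maximum(i, 0)], 0.0,
                         (b - a)[np.maximum(i, 0)])
        return np.where(i >= 0, cum[np.maximum(i, 0)] + inside, 0.0)

    frac = (covered_upto(starts + width) - covered_upto(starts)) / width
    return np.clip(frac, 0.0, 1.0)


# ---------------------------------------------------------------------------
# waveform tier
# ---------------------------------------------------------------------------

def generate_recording(spec: PatientSpec,
                       template: MorphologyTemplate | None = None,
                       ) -> tuple[EcgRecording, GroundTruth]:
    """Render a 200 Hz 12-lead recording plus full ground truth.

    Memory scales with duration (about 0.5 GB/day at float32); use the series
    tier for day-scale cohort studies.
    """
    fs = 200.0
    template = template or MorphologyTemplate(qrs_ms=spec.qrs_ms)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    dur_s = spec.duration_s
    n = int(round(dur_s * fs))
    sig = np.zeros((n, len(LEADS)), dtype=np.float32)

    prone, episodes = _draw_episodes(spec, rng)

    # beat schedule
    beat_times, is_ectopic = [], []
    t = 0.4
    while t < dur_s - 0.8:
        beat_times.append(t)
        ect = bool(rng.random() < spec.ectopic_prob)
        is_ectopic.append(ect)
        hr = float(spec.hr_at(t))
        rr = 60.0 / max(hr, 20.0) + rng.normal(0.0, spec.rr_jitter_ms) / 1000.0
        rr = max(rr, 0.3)
        if ect:
            rr *= 0.75
        t += rr
    beat_times = np.asarray(beat_times)
    is_ectopic = np.asarray(is_ectopic, bool)

    pq_arr = spec.pq_at(beat_times)
    rr_prev = np.empty_like(beat_times)
    rr_prev[1:] = np.diff(beat_times) * 1000.0
    rr_prev[0] = 60000.0 / float(spec.hr_at(beat_times[0]))
    qt_arr = spec.qt_from_rr(rr_prev, beat_times)

    st_vec = np.zeros(len(LEADS))
    t_vec = np.ones(len(LEADS))
    ep_starts = np.array([e.start_s for e in episodes])
    ep_ends = np.array([e.end_s for e in episodes])
    for i, bt in enumerate(beat_times):
        st_vec[:] = 0.0
        t_vec[:] = 1.0
        any_ep = False
        if episodes:
            for k in np.nonzero((ep_starts < bt) & (ep_ends > bt))[0]:
                ep = episodes[k]
                fac = ep.envelope(bt)
                if fac <= 0:
                    continue
                idx = [LEAD_INDEX[l] for l in ep.leads]
                if ep.kind == "st_offset":
                    st_vec[idx] += ep.amplitude_mv * fac
                else:
                    t_vec[idx] += ep.amplitude_mv / max(template.t_amp_mv, 1e-6) * fac
                any_ep = True
        rel, wave = template.render_beat(
            fs, pq_ms=float(pq_arr[i]), qt_ms=float(qt_arr[i]),
            st_offset_mv=st_vec if any_ep else None,
            t_scale=t_vec if any_ep else None,
            ectopic=bool(is_ectopic[i]))
        s0 = int(round(bt * fs)) + rel
        s1 = s0 + wave.shape[0]
        a, b = max(s0, 0), min(s1, n)
        if b > a:
            sig[a:b] += wave[a - s0: b - s0].astype(np.float32)

    # band-limited measurement noise
    if spec.noise_rms_mv > 0:
        sos = sps.butter(2, 40.0 / (fs / 2.0), output="sos")
        for j in range(len(LEADS)):
            w = rng.normal(0.0, 1.0, n)
            w = sps.sosfiltfilt(sos, w)
            w *= spec.noise_rms_mv / max(np.sqrt(np.mean(w * w)), 1e-12)
            sig[:, j] += w.astype(np.float32)

    # artifact bursts
    artifacts = _draw_artifacts(spec, rng)
    for a, b in artifacts:
        i0, i1 = int(a * fs), min(int(b * fs), n)
        if i1 > i0:
            sig[i0:i1] += rng.normal(
                0.0, spec.artifact_amp_mv, (i1 - i0, len(LEADS))
            ).astype(np.float32)

    # gaps: zero-filled, flagged
    gaps = spec.gap_intervals()
    for a, b in gaps:
        sig[int(a * fs): int(b * fs)] = 0.0

    in_gap = np.zeros(len(beat_times), bool)
    for a, b in gaps:
        in_gap |= (beat_times >= a - 0.5) & (beat_times < b + 0.5)

    rec = EcgRecording(signal=sig, fs=fs, leads=LEADS,
                       start_time=spec.start_time, gaps=gaps)
    truth = GroundTruth(
        spec=spec, episodes=episodes,
        beat_times=beat_times[~in_gap],
        beat_is_ectopic=is_ectopic[~in_gap],
        beat_pq_ms=pq_arr[~in_gap], beat_qt_ms=qt_arr[~in_gap],
        artifact_intervals=artifacts, gaps=gaps, ischemia_prone=prone)
    return rec, truth


# ---------------------------------------------------------------------------
# symptom log
# ---------------------------------------------------------------------------

def generate_symptom_log(spec: PatientSpec, truth: GroundTruth,
                         patient_id: str = "P000") -> pd.DataFrame:
    """Emit diary and button streams for one patient.

    True symptoms are background (Poisson over the recording) plus, with
    probability ``episode_symptom_prob``, one symptom within +/-20 min of
    each injected episode onset.  Each true symptom is then reported to the
    diary and the button independently with the configured probabilities, so
    some symptoms appear in both streams, some in one, some in neither.
    Updates ``truth.symptoms`` in place.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))
    dur = spec.duration_s
    events: list[SymptomEvent] = []
    n_bg = rng.poisson(spec.background_symptom_rate_per_day
                       * spec.duration_days)
    bg_times = np.sort(rng.uniform(0.0, dur, n_bg))
    bg_types = rng.choice(SYMPTOM_TYPES, size=n_bg,
                          p=[0.40, 0.25, 0.20, 0.15])
    for t, ty in zip(bg_times, bg_types):
        events.append(SymptomEvent(float(t), str(ty), from_episode=False))
    for ep in truth.episodes:
        if rng.random() < spec.episode_symptom_prob:
            t = ep.start_s + rng.uniform(-20.0, 20.0) * 60.0
            t = float(np.clip(t, 0.0, dur - 1.0))
            ty = str(rng.choice(ACUTE_SYMPTOM_TYPES, p=[0.7, 0.3]))
            events.append(SymptomEvent(t, ty, from_episode=True))
    events.sort(key=lambda e: e.time_s)
    truth.symptoms = events

    rows = []
    for ev in events:
        in_diary = rng.random() < spec.diary_prob
        in_button = rng.random() < spec.button_prob
        dur_min = float(np.round(np.exp(rng.normal(np.log(10.0), 0.6)), 1))
        if in_diary:
            rows.append((patient_id, "diary",
                         spec.start_time + timedelta(seconds=ev.time_s),
                         ev.type, dur_min))
        if in_button:
            jitter = rng.normal(0.0, spec.button_jitter_min) * 60.0
            tt = float(np.clip(ev.time_s + jitter, 0.0, dur - 1.0))
            rows.append((patient_id, "button",
                         spec.start_time + timedelta(seconds=tt),
                         ev.type, np.nan))
    log = pd.DataFrame(rows, columns=["patient_id", "source", "timestamp",
                                      "type", "duration_min"])
    return log.sort_values("timestamp", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# series tier
# ---------------------------------------------------------------------------

@dataclass
class PatientSeries:
    """Series-tier bundle for one patient: what segmentation + median-beat
    analysis would produce, generated directly from the patient model."""

    patient_id: str
    label: str
    spec: PatientSpec
    intervals: IntervalSeries
    sdnn: SdnnSeries
    deviations: DeviationSeries
    symptoms: pd.DataFrame
    truth: GroundTruth


def generate_patient_series(spec: PatientSpec, patient_id: str = "P000",
                            ) -> PatientSeries:
    """Emit per-10-s interval and deviation series plus symptom log directly
    from the patient model (no waveform synthesis)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    prone, episodes = _draw_episodes(spec, rng)
    gaps = spec.gap_intervals()
    artifacts = _draw_artifacts(spec, rng)

    n_seg = int(spec.duration_s // SEGMENT_SECONDS)
    seg_start = np.arange(n_seg) * SEGMENT_SECONDS
    seg_mid = seg_start + SEGMENT_SECONDS / 2.0

    hr = spec.hr_at(seg_mid) + rng.normal(0.0, 1.5, n_seg)
    hr = np.clip(hr, 30.0, 190.0)
    rr_ms = 60000.0 / hr
    pq = spec.pq_at(seg_mid) + rng.normal(0.0, 2.0, n_seg)
    qrs = spec.qrs_ms + rng.normal(0.0, 1.5, n_seg)
    qt = spec.qt_from_rr(rr_ms, seg_mid) + rng.normal(0.0, 4.0, n_seg)
    beat_count = np.maximum(
        1, np.round(SEGMENT_SECONDS * hr / 60.0)).astype(int)

    gap_frac = _interval_overlap_fraction(seg_start, SEGMENT_SECONDS, gaps)
    art_frac = _interval_overlap_fraction(seg_start, SEGMENT_SECONDS, artifacts)
    usable = (gap_frac == 0.0) & (art_frac < 0.5)

    for arr in (hr, pq, qrs, qt):
        arr[~usable] = np.nan

    intervals = IntervalSeries(
        window_start=seg_start, hr_bpm=hr, pq_ms=pq, qrs_ms=qrs, qt_ms=qt,
        beat_count=beat_count, usable=usable, start_time=spec.start_time)

    # SDNN per 5 min: RR jitter dominates; circadian drift is slow
    n5 = int(spec.duration_s // 300.0)
    s5 = np.arange(n5) * 300.0
    g5 = _interval_overlap_fraction(s5, 300.0, gaps)
    a5 = _interval_overlap_fraction(s5, 300.0, artifacts)
    nn = np.round((1.0 - np.maximum(g5, a5)) * 300.0
                  * spec.hr_at(s5 + 150.0) / 60.0).astype(int)
    sdnn = np.abs(rng.normal(max(spec.rr_jitter_ms, 1.0), 5.0, n5))
    sdnn[nn < 30] = np.nan
    sdnn_series = SdnnSeries(window_start=s5, sdnn_ms=sdnn, nn_count=nn,
                             start_time=spec.start_time)

    # deviation series: measurement noise + injected episodes
    st = rng.normal(0.0, spec.st_noise_sd_mv, (n_seg, len(LEADS)))
    tmin = rng.normal(0.0, spec.st_noise_sd_mv, (n_seg, len(LEADS)))
    tmax = rng.normal(0.0, spec.st_noise_sd_mv, (n_seg, len(LEADS)))
    for ep in episodes:
        i0 = max(0, int(ep.start_s // SEGMENT_SECONDS))
        i1 = min(n_seg, int(np.ceil(ep.end_s / SEGMENT_SECONDS)))
        if i1 <= i0:
            continue
        idx = [LEAD_INDEX[l] for l in ep.leads]
        for i in range(i0, i1):
            cov = (min(seg_start[i] + SEGMENT_SECONDS, ep.end_s)
                   - max(seg_start[i], ep.start_s)) / SEGMENT_SECONDS
            fac = ep.envelope(float(seg_mid[i])) * max(cov, 0.0)
            if fac <= 0:
                continue
            if ep.kind == "st_offset":
                st[i, idx] += ep.amplitude_mv * fac
            else:
                tmax[i, idx] += ep.amplitude_mv * fac
                tmin[i, idx] += 0.3 * ep.amplitude_mv * fac
    st[~usable] = np.nan
    tmin[~usable] = np.nan
    tmax[~usable] = np.nan
    bbin = np.full(n_seg, -1, dtype=int)
    ok = usable & np.isfinite(hr)
    bbin[ok] = np.clip(np.round((hr[ok] - 40.0) / 5.0), 0, 20).astype(int)

    deviations = DeviationSeries(
        segment_start=seg_start, st=st, tmin=tmin, tmax=tmax,
        usable=usable, baseline_bin=bbin, start_time=spec.start_time)

    truth = GroundTruth(spec=spec, episodes=episodes, gaps=gaps,
                        artifact_intervals=artifacts, ischemia_prone=prone)
    symptoms = generate_symptom_log(spec, truth, patient_id=patient_id)
    return PatientSeries(patient_id=patient_id, label=spec.group, spec=spec,
                         intervals=intervals, sdnn=sdnn_series,
                         deviations=deviations, symptoms=symptoms,
                         truth=truth)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def default_cas_spec(**overrides) -> PatientSpec:
    """Study conditions for the CAS arm: lower, more variable nocturnal heart
    rate, longer PQ/QTc, frequent ischemia-prone patients, symptoms partly
    tied to episodes."""
    base = dict(
        group="CAS", hr_mesor_bpm=70.0, hr_amplitude_bpm=10.0,
        pq_base_ms=166.0, pq_nocturnal_ms=14.0, qtc_base_ms=451.0,
        ischemia_prone_prob=0.88, episode_rate_per_day=4.0,
        episode_symptom_prob=0.5,
    )
    base.update(overrides)
    return PatientSpec(**base)


def default_nocas_spec(**overrides) -> PatientSpec:
    """Study conditions for the no-CAS arm: higher nocturnal heart rate,
    shorter PQ/QTc, ischemia-prone patients still present (the low-specificity
    phenomenon) but less frequent."""
    base = dict(
        group="no_CAS", hr_mesor_bpm=73.0, hr_amplitude_bpm=7.5,
        pq_base_ms=153.0, pq_nocturnal_ms=8.0, qtc_base_ms=440.0,
        ischemia_prone_prob=0.44, episode_rate_per_day=4.0,
        episode_symptom_prob=0.5,
    )
    base.update(overrides)
    return PatientSpec(**base)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1, np.uint32)[0] % (2 ** 31))
            for c in ss.spawn(n)]


def _jitter_spec(spec: PatientSpec, seed: int) -> PatientSpec:
    """Apply between-patient parameter variation, deterministically per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    changes = {"seed": int(seed)}
    for name, sd in spec.bp_sd.items():
        if sd > 0:
            changes[name] = float(getattr(spec, name) + rng.normal(0.0, sd))
    sp = replace(spec, **changes)
    return sp


def iter_cohort(n_cas: int, n_nocas: int,
                cas_spec: PatientSpec | None = None,
                nocas_spec: PatientSpec | None = None,
                seed: int = 0,
                between_patient_variation: bool = True,
                ):
    """Yield a labelled two-group cohort patient by patient (series tier).

    Per-patient seeds derive deterministically from the master seed; group
    specs are applied by label, with optional between-patient parameter
    jitter.  Streaming keeps memory flat for large cohorts.
    """
    if n_cas < 1 or n_nocas < 1:
        raise ValueError("need at least one patient per group")
    cas_spec = cas_spec or default_cas_spec()
    nocas_spec = nocas_spec or default_nocas_spec()
    seeds = _spawn_seeds(seed, n_cas + n_nocas)
    for i in range(n_cas + n_nocas):
        base = cas_spec if i < n_cas else nocas_spec
        sp = (_jitter_spec(base, seeds[i]) if between_patient_variation
              else replace(base, seed=seeds[i]))
        yield generate_patient_series(sp, patient_id=f"P{i:03d}")


def generate_cohort(n_cas: int, n_nocas: int,
                    cas_spec: PatientSpec | None = None,
                    nocas_spec: PatientSpec | None = None,
                    seed: int = 0,
                    between_patient_variation: bool = True,
                    ) -> list[PatientSeries]:
    """Materialised :func:`iter_cohort` (use the iterator for large n)."""
    return list(iter_cohort(n_cas, n_nocas, cas_spec, nocas_spec, seed,
                            between_patient_variation))
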