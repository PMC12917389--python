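"""Ischemia events, burden and symptom concurrency.

An ischemia event for a parameter/cutoff is a maximal run of at least three
consecutive usable 10-s segments (>= 30 s) during which the cutoff is
exceeded in at least two contiguous leads.  Under the default ``pair_stable``
rule the *same* contiguous pair must exceed throughout the run; the looser
``any_pair`` reading (some contiguous pair each segment) is available as a
config switch.

Burden is the total event duration normalised to seconds per 24 h of usable
recording; the headline flag is >= 1 min (60 s) of daily ischemia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .containers import (ACUTE_SYMPTOM_TYPES, DeviationSeries,
                         ISCHEMIA_PARAMETERS, SEGMENT_SECONDS)
from .leads import CONTIGUOUS_PAIRS, LEADS, pair_indices


@dataclass
class IschemiaEvent:
    parameter: str
    cutoff_mv: float
    start_s: float
    end_s: float
    leads: tuple[str, ...]
    peak_deviation_mv: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BurdenSummary:
    parameter: str
    cutoff_mv: float
    total_event_s: float
    usable_s: float
    normalized_s_per_day: float
    flag_1min: bool


@dataclass
class ConcurrencyResult:
    cutoff_mv: float
    n_acute_symptoms: int
    n_concurrent: int
    pct_concurrent: Optional[float]
    flag_any_concurrent: bool


def exceedance(dev: DeviationSeries, parameter: str, cutoff_mv: float,
               ) -> np.ndarray:
    """(n_segments, 12) boolean exceedance matrix; NaN never exceeds."""
    if parameter not in ISCHEMIA_PARAMETERS:
        raise ValueError(f"unknown ischemia parameter: {parameter!r}")
    if cutoff_mv < 0:
        raise ValueError("cutoff must be >= 0")
    x = dev.measure(parameter)
    with np.errstate(invalid="ignore"):
        if parameter == "st_depression":
            e = x <= -cutoff_mv
        elif parameter == "st_elevation":
            e = x >= cutoff_mv
        else:
            e = np.abs(x) >= cutoff_mv
    e &= dev.usable[:, None]
    return e


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_events(dev: DeviationSeries, parameter: str, cutoff_mv: float,
                  config: PipelineConfig = DEFAULT_CONFIG,
                  ) -> list[IschemiaEvent]:
    """Detect ischemia events on the 10-s segment grid.

    Unusable segments break runs.  Event lead sets are the union of the leads
    of every contiguous pair that sustains a qualifying run inside the event.
    """
    e = exceedance(dev, parameter, cutoff_mv)
    n = e.shape[0]
    min_seg = config.min_event_segments
    pairs = pair_indices()

    qualifying = np.zeros(n, bool)
    pair_runs: list[tuple[int, int, int]] = []  # (pair_idx, start, end)
    if config.contiguity_rule == "pair_stable":
        for pi, (i, j) in enumerate(pairs):
            both = e[:, i] & e[:, j]
            for a, b in _runs(both):
                if b - a >= min_seg:
                    qualifying[a:b] = True
                    pair_runs.append((pi, a, b))
    else:  # any_pair: some contiguous pair exceeds in each segment
        any_pair = np.zeros(n, bool)
        for i, j in pairs:
            any_pair |= e[:, i] & e[:, j]
        for a, b in _runs(any_pair):
            if b - a >= min_seg:
                qualifying[a:b] = True
        for pi, (i, j) in enumerate(pairs):
            both = e[:, i] & e[:, j]
            for a, b in _runs(both):
                pair_runs.append((pi, a, b))

    x = dev.measure(parameter)
    events = []
    seg0 = dev.segment_start
    for a, b in _runs(qualifying):
        leadset: set[str] = set()
        for pi, ra, rb in pair_runs:
            if ra >= a and rb <= b and (config.contiguity_rule != "pair_stable"
                                        or rb - ra >= min_seg):
                leadset.update(CONTIGUOUS_PAIRS[pi])
            elif config.contiguity_rule == "any_pair" and ra < b and rb > a:
                leadset.update(CONTIGUOUS_PAIRS[pi])
        lead_ix = [LEADS.index(l) for l in sorted(leadset, key=LEADS.index)]
        block = x[a:b][:, lead_ix]
        finite = block[np.isfinite(block)]
        peak = float(finite[np.argmax(np.abs(finite))]) if finite.size else np.nan
        events.append(IschemiaEvent(
            parameter=parameter, cutoff_mv=float(cutoff_mv),
            start_s=float(seg0[a]),
            end_s=float(seg0[b - 1] + SEGMENT_SECONDS),
            leads=tuple(sorted(leadset, key=LEADS.index)),
            peak_deviation_mv=peak))
    return events


def burden(events: Sequence[IschemiaEvent], usable_s: float,
           parameter: str = "st_depression", cutoff_mv: float = 0.035,
           config: PipelineConfig = DEFAULT_CONFIG) -> BurdenSummary:
    """Normalised daily burden: total event duration scaled to s per 24 h of
    usable recording; flag at >= 60 s/day."""
    if usable_s <= 0:
        raise ValueError("usable duration must be positive")
    total = float(sum(ev.duration_s for ev in events))
    norm = total * 86400.0 / usable_s
    return BurdenSummary(parameter=parameter, cutoff_mv=cutoff_mv,
                         total_event_s=total, usable_s=float(usable_s),
                         normalized_s_per_day=norm,
                         flag_1min=norm >= config.burden_flag_s_per_day)


def patient_burden(dev: DeviationSeries, parameter: str, cutoff_mv: float,
                   config: PipelineConfig = DEFAULT_CONFIG) -> BurdenSummary:
    usable_s = float(dev.usable.sum() * SEGMENT_SECONDS)
    events = detect_events(dev, parameter, cutoff_mv, config)
    return burden(events, usable_s, parameter, cutoff_mv, config)


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    parameter: str
    cutoffs_mv: np.ndarray
    flags: np.ndarray          # (n_patients, n_cutoffs) bool
    burdens: np.ndarray        # (n_patients, n_cutoffs) s/day
    labels: np.ndarray         # bool, True = CAS
    patient_ids: list[str] = field(default_factory=list)


def threshold_sweep(deviations: Sequence[DeviationSeries],
                    labels: Sequence[bool],
                    parameter: str = "st_depression",
                    cutoffs_mv: Optional[np.ndarray] = None,
                    config: PipelineConfig = DEFAULT_CONFIG,
                    patient_ids: Optional[Sequence[str]] = None,
                    ) -> SweepResult:
    """Per-cutoff burden flags for every patient.

    Flags are monotone non-increasing in the cutoff for each patient, since
    exceedance sets only shrink as the cutoff rises.
    """
    if cutoffs_mv is None:
        cutoffs_mv = config.cutoffs()
    cutoffs_mv = np.asarray(cutoffs_mv, float)
    n_p, n_c = len(deviations), cutoffs_mv.size
    flags = np.zeros((n_p, n_c), bool)
    burdens = np.zeros((n_p, n_c))
    for p, dev in enumerate(deviations):
        for c, cut in enumerate(cutoffs_mv):
            bs = patient_burden(dev, parameter, float(cut), config)
            flags[p, c] = bs.flag_1min
            burdens[p, c] = bs.normalized_s_per_day
    return SweepResult(parameter=parameter, cutoffs_mv=cutoffs_mv,
                       flags=flags, burdens=burdens,
                       labels=np.asarray(labels, bool),
                       patient_ids=list(patient_ids or
                                        [f"P{i:03d}" for i in range(n_p)]))


# ---------------------------------------------------------------------------
# symptoms
# ---------------------------------------------------------------------------

def merge_symptoms(log: pd.DataFrame, start_time: datetime,
                   config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Merge diary and button streams into unique symptoms.

    Events of the same type within the dedup window (10 min) are one symptom;
    the diary timestamp is kept when both sources report it.  Returns a frame
    with columns ``time_s`` (seconds from recording start), ``type``,
    ``sources``.
    """
    if log.empty:
        return pd.DataFrame(columns=["time_s", "type", "sources"])
    df = log.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["time_s"] = (ts - pd.Timestamp(start_time)).dt.total_seconds()
    df = df.sort_values(["time_s"], kind="stable")
    window = config.symptom_dedup_min * 60.0
    merged: list[dict] = []
    for _, row in df.iterrows():
        hit = None
        for m in reversed(merged):
            if (m["type"] == row["type"]
                    and abs(m["raw_time"] - row["time_s"]) <= window):
                hit = m
                break
        if hit is None:
            merged.append({"raw_time": row["time_s"],
                           "time_s": row["time_s"], "type": row["type"],
                           "sources": {row["source"]}})
        else:
            # keep the diary timestamp when both sources report one symptom
            if row["source"] == "diary" and "diary" not in hit["sources"]:
                hit["time_s"] = row["time_s"]
            hit["sources"].add(row["source"])
    out = pd.DataFrame([{"time_s": m["time_s"], "type": m["type"],
                         "sources": ",".join(sorted(m["sources"]))}
                        for m in merged])
    return out.sort_values("time_s").reset_index(drop=True)


def symptom_concurrency(events: Sequence[IschemiaEvent],
                        merged_symptoms: pd.DataFrame,
                        cutoff_mv: float = 0.035,
                        config: PipelineConfig = DEFAULT_CONFIG,
                        ) -> ConcurrencyResult:
    """Fraction of acute symptoms (chest pain / dyspnea) with at least one
    ischemia event within +/-30 min of symptom onset (boundary inclusive).

    Patients with zero acute symptoms yield an absent percentage and a false
    flag, so they can still enter the diagnostic 2x2 tables.
    """
    w = config.concurrency_window_min * 60.0
    if merged_symptoms.empty:
        acute = merged_symptoms
    else:
        acute = merged_symptoms[
            merged_symptoms["type"].isin(ACUTE_SYMPTOM_TYPES)]
    n = len(acute)
    if n == 0:
        return ConcurrencyResult(cutoff_mv=cutoff_mv, n_acute_symptoms=0,
                                 n_concurrent=0, pct_concurrent=None,
                                 flag_any_concurrent=False)
    starts = np.array([ev.start_s for ev in events])
    ends = np.array([ev.end_s for ev in events])
    conc = 0
    for t in acute["time_s"].to_numpy(float):
        if starts.size and np.any((starts <= t + w) & (ends >= t - w)):
            conc += 1
    return ConcurrencyResult(cutoff_mv=cutoff_mv, n_acute_symptoms=n,
                             n_concurrent=conc,
                             pct_concurrent=100.0 * conc / n,
                             flag_any_concurrent=conc > 0)
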