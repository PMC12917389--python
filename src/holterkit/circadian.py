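"""24-hour and 10-second assessments.

* noon-to-noon day selection (first/last full day, with a minimum usable
  fraction),
* circadian profiles: per-3-h-bin medians of HR, PQ, QRS, QT, QTc and SDNN,
  with group-level medians and 2.5th-97.5th percentile bands,
* per-bin group comparison (Shapiro-Wilk gate: Welch t-test when both groups
  look normal, Mann-Whitney U otherwise),
* unadjusted/adjusted logistic regression for features that separate groups,
* resting 10-s selection: symptom-free 06:30-08:30 window with heart rate
  closest to 75 bpm, and Bazett QT correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig
from .containers import IntervalSeries, SdnnSeries, SEGMENT_SECONDS

log = logging.getLogger(__name__)

MEASURES = ("hr_bpm", "pq_ms", "qrs_ms", "qt_ms", "qtc_ms", "sdnn_ms")


def qtc_bazett(qt_ms: float | np.ndarray, rr_ms: float | np.ndarray):
    """Bazett-corrected QT: QT / sqrt(RR in seconds)."""
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR must be positive")
    out = np.asarray(qt_ms, dtype=float) / np.sqrt(rr / 1000.0)
    return float(out) if out.ndim == 0 else out


def qtc_prolonged(qtc_ms: float, sex: str,
                  config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    """Prolonged-QTc flag at the conventional 460 ms (F) / 450 ms (M)."""
    key = sex.strip().upper()[:1]
    if key not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    return qtc_ms >= config.qtc_prolonged_ms[key]


# ---------------------------------------------------------------------------
# day windows
# ---------------------------------------------------------------------------

@dataclass
class DayWindow:
    which: str            # "first_full" | "last_full"
    start_s: float
    end_s: float
    start_time: datetime  # wall-clock noon starting the window


def select_day_window(intervals: IntervalSeries, which: str = "last_full",
                      config: PipelineConfig = DEFAULT_CONFIG) -> DayWindow:
    """Earliest/latest complete noon-to-noon day with enough usable signal.

    A day qualifies when at least ``day_usable_min_fraction`` of its 10-s
    windows are usable.  Raises ``ValueError`` when no day qualifies.
    """
    if which not in ("first_full", "last_full"):
        raise ValueError("which must be first_full or last_full")
    duration = (float(intervals.window_start[-1]) + SEGMENT_SECONDS
                if len(intervals) else 0.0)
    start_clock = (intervals.start_time.hour * 3600
                   + intervals.start_time.minute * 60
                   + intervals.start_time.second)
    first_noon = (12 * 3600 - start_clock) % 86400
    candidates = []
    t = float(first_noon)
    while t + 86400.0 <= duration + 1e-9:
        m = (intervals.window_start >= t) & (intervals.window_start < t + 86400.0)
        frac = intervals.usable[m].mean() if m.any() else 0.0
        if frac >= config.day_usable_min_fraction:
            candidates.append(t)
        t += 86400.0
    if not candidates:
        raise ValueError("no complete qualifying noon-to-noon day in recording")
    t0 = candidates[0] if which == "first_full" else candidates[-1]
    return DayWindow(which=which, start_s=t0, end_s=t0 + 86400.0,
                     start_time=intervals.start_time + timedelta(seconds=t0))


# ---------------------------------------------------------------------------
# circadian profile
# ---------------------------------------------------------------------------

def circadian_profile(intervals: IntervalSeries, sdnn: SdnnSeries,
                      window: DayWindow,
                      config: PipelineConfig = DEFAULT_CONFIG,
                      ) -> pd.DataFrame:
    """Per-3-h-bin medians for one patient over one noon-to-noon day.

    Bins are indexed 0..7 from midnight (bin 0 = 12-3 AM).  Bin medians are
    absent with fewer than ``bin_min_windows`` usable windows.
    """
    n_bins = int(round(24.0 / config.bin_hours))
    m = ((intervals.window_start >= window.start_s)
         & (intervals.window_start < window.end_s))
    hours = intervals.clock_hours()[m]
    bins = (hours // config.bin_hours).astype(int) % n_bins
    usable = intervals.usable[m]

    vals = {
        "hr_bpm": intervals.hr_bpm[m],
        "pq_ms": intervals.pq_ms[m],
        "qrs_ms": intervals.qrs_ms[m],
        "qt_ms": intervals.qt_ms[m],
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = 60000.0 / intervals.hr_bpm[m]
        vals["qtc_ms"] = np.where(rr > 0,
                                  intervals.qt_ms[m] / np.sqrt(rr / 1000.0),
                                  np.nan)

    base5 = (window.start_time.hour * 3600 + window.start_time.minute * 60
             + window.start_time.second)
    m5 = ((sdnn.window_start >= window.start_s)
          & (sdnn.window_start < window.end_s))
    s_clk = (( (sdnn.start_time.hour * 3600 + sdnn.start_time.minute * 60
                + sdnn.start_time.second) + sdnn.window_start[m5]) % 86400.0)
    s_bins = ((s_clk / 3600.0) // config.bin_hours).astype(int) % n_bins
    s_vals = sdnn.sdnn_ms[m5]

    rows = []
    for b in range(n_bins):
        sel = (bins == b) & usable
        row = {"bin": b,
               "bin_start_h": b * config.bin_hours,
               "n_windows": int(sel.sum())}
        for meas in ("hr_bpm", "pq_ms", "qrs_ms", "qt_ms", "qtc_ms"):
            v = vals[meas][sel]
            v = v[np.isfinite(v)]
            row[meas] = (float(np.median(v))
                         if sel.sum() >= config.bin_min_windows and v.size
                         else np.nan)
        sv = s_vals[s_bins == b]
        sv = sv[np.isfinite(sv)]
        row["sdnn_ms"] = float(np.median(sv)) if sv.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def group_profile(profiles: Sequence[pd.DataFrame], labels: Sequence[bool],
                  ) -> pd.DataFrame:
    """Group-level median and 2.5th/97.5th percentiles across patients."""
    rows = []
    all_bins = sorted(profiles[0]["bin"]) if profiles else []
    labels = np.asarray(labels, bool)
    for b in all_bins:
        for meas in MEASURES:
            for grp, name in ((True, "CAS"), (False, "no_CAS")):
                v = np.array([p.loc[p["bin"] == b, meas].iloc[0]
                              for p, l in zip(profiles, labels) if l == grp])
                v = v[np.isfinite(v)]
                if v.size == 0:
                    continue
                rows.append({"bin": b, "measure": meas, "group": name,
                             "n": v.size, "median": float(np.median(v)),
                             "p2.5": float(np.percentile(v, 2.5)),
                             "p97.5": float(np.percentile(v, 97.5))})
    return pd.DataFrame(rows)


def _two_group_test(a: np.ndarray, b: np.ndarray, shapiro_alpha: float,
                    ) -> tuple[str, float, float]:
    """Welch t-test when both groups pass Shapiro-Wilk, else Mann-Whitney."""
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return ("none", np.nan, np.nan)
    if np.ptp(np.concatenate([a, b])) == 0:
        return ("mannwhitney", np.nan, 1.0)  # all values identical

    def _normal(x):
        if x.size < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > shapiro_alpha

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return ("welch_t", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ("mannwhitney", float(res.statistic), float(res.pvalue))


def compare_bins(profiles: Sequence[pd.DataFrame], labels: Sequence[bool],
                 config: PipelineConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-bin, per-measure two-group comparison across patients."""
    labels = np.asarray(labels, bool)
    rows = []
    bins = sorted(profiles[0]["bin"]) if len(profiles) else []
    for b in bins:
        for meas in MEASURES:
            v = np.array([p.loc[p["bin"] == b, meas].iloc[0]
                          for p in profiles])
            test, statv, p = _two_group_test(
                v[labels], v[~labels], config.shapiro_alpha)
            if test == "none":
                continue
            rows.append({"bin": b, "measure": meas, "test": test,
                         "statistic": statv, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticResult:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    adjusted: bool
    n: int
    flagged: Optional[str] = None   # "separation" | "non_convergence"


def _fit_logit(y: np.ndarray, X: np.ndarray, adjusted: bool,
               ) -> LogisticResult:
    n = len(y)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = fit.params[1]
        if not fit.mle_retvals.get("converged", False):
            return LogisticResult(None, None, None, None, adjusted, n,
                                  flagged="non_convergence")
        if abs(beta) > 15 or fit.bse[1] > 50:
            return LogisticResult(None, None, None, None, adjusted, n,
                                  flagged="separation")
        ci = fit.conf_int()[1]
        return LogisticResult(float(np.exp(beta)), float(np.exp(ci[0])),
                              float(np.exp(ci[1])), float(fit.pvalues[1]),
                              adjusted, n)
    except Exception as exc:  # perfect separation raises in statsmodels
        name = type(exc).__name__
        flag = "separation" if "Separation" in name else "non_convergence"
        return LogisticResult(None, None, None, None, adjusted, n,
                              flagged=flag)


def adjusted_logistic(feature: np.ndarray, label: np.ndarray,
                      covariates: Optional[pd.DataFrame] = None,
                      ) -> dict[str, LogisticResult]:
    """Odds ratio per unit feature for the CAS label, unadjusted and adjusted
    for the supplied covariates (age, sex, beta-blocker use, rate-limiting
    calcium-channel-blocker use in the standard analysis)."""
    y = np.asarray(label, float)
    x = np.asarray(feature, float)
    keep = np.isfinite(x) & np.isfinite(y)
    if covariates is not None:
        keep &= np.isfinite(covariates.to_numpy(float)).all(axis=1)
    y, x = y[keep], x[keep]
    X0 = sm.add_constant(x)
    out = {"unadjusted": _fit_logit(y, X0, adjusted=False)}
    if covariates is not None:
        C = covariates.loc[keep].to_numpy(float)
        X1 = np.column_stack([np.ones(len(x)), x, C])
        out["adjusted"] = _fit_logit(y, X1, adjusted=True)
    return out


# ---------------------------------------------------------------------------
# resting 10-s selection
# ---------------------------------------------------------------------------

@dataclass
class RestingTenSeconds:
    segment_start_s: float
    clock_time: datetime
    hr_bpm: float
    pq_ms: float
    qrs_ms: float
    qt_ms: float
    qtc_ms: float


def _parse_clock(s: str) -> float:
    h, m = s.split(":")
    return int(h) * 3600.0 + int(m) * 60.0


def select_resting_10s(intervals: IntervalSeries,
                       merged_symptoms: pd.DataFrame,
                       preferred_dates: Optional[Sequence[date]] = None,
                       config: PipelineConfig = DEFAULT_CONFIG,
                       ) -> Optional[RestingTenSeconds]:
    """Choose the 10-s resting window: usable, symptom-free (no merged
    symptom within +/-15 min), clock time 06:30-08:30, heart rate closest to
    75 bpm; ties break to the earliest window.  Days are tried in preference
    order (by default the day before the recording ends, then the day before
    that); returns None when no day has a candidate."""
    if not len(intervals):
        return None
    end_dt = intervals.start_time + timedelta(
        seconds=float(intervals.window_start[-1]))
    if preferred_dates is None:
        preferred_dates = [end_dt.date() - timedelta(days=1),
                           end_dt.date() - timedelta(days=2)]
    band_lo = _parse_clock(config.resting_band[0])
    band_hi = _parse_clock(config.resting_band[1])
    sym_t = (merged_symptoms["time_s"].to_numpy(float)
             if len(merged_symptoms) else np.empty(0))
    margin = config.resting_symptom_margin_min * 60.0

    start_clock = (intervals.start_time.hour * 3600
                   + intervals.start_time.minute * 60
                   + intervals.start_time.second)
    for day in preferred_dates:
        day_offset = (datetime.combine(day, time(0, 0))
                      - intervals.start_time).total_seconds()
        lo, hi = day_offset + band_lo, day_offset + band_hi
        m = ((intervals.window_start >= lo) & (intervals.window_start < hi)
             & intervals.usable & np.isfinite(intervals.hr_bpm))
        idx = np.nonzero(m)[0]
        if sym_t.size:
            ok = np.array([
                not np.any(np.abs(sym_t - intervals.window_start[i]) <= margin)
                for i in idx], dtype=bool)
            idx = idx[ok]
        if idx.size == 0:
            continue
        hr = intervals.hr_bpm[idx]
        best = idx[np.lexsort((intervals.window_start[idx],
                               np.abs(hr - config.resting_target_bpm)))][0]
        hrv = float(intervals.hr_bpm[best])
        qt = float(intervals.qt_ms[best])
        rr = 60000.0 / hrv
        return RestingTenSeconds(
            segment_start_s=float(intervals.window_start[best]),
            clock_time=intervals.start_time + timedelta(
                seconds=float(intervals.window_start[best])),
            hr_bpm=hrv, pq_ms=float(intervals.pq_ms[best]),
            qrs_ms=float(intervals.qrs_ms[best]), qt_ms=qt,
            qtc_ms=qtc_bazett(qt, rr) if np.isfinite(qt) else np.nan)
    log.info("no eligible resting 10-s window on any preferred day")
    return None
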