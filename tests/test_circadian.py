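"""Day-window selection, circadian profiles, group tests, logistic models,
resting 10-s selection and Bazett QTc."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holterkit import (IntervalSeries, SdnnSeries, adjusted_logistic,
                       circadian_profile, compare_bins, qtc_bazett,
                       qtc_prolonged, select_day_window, select_resting_10s)
from holterkit.circadian import _two_group_test
from holterkit.config import DEFAULT_CONFIG
from holterkit.containers import SEGMENT_SECONDS
from holterkit.synthetic import default_cas_spec, generate_patient_series


def mk_intervals(start: datetime, hours: float, hr=70.0, usable=True,
                 pq=160.0, qrs=92.0, qt=400.0) -> IntervalSeries:
    n = int(hours * 360)
    hr_arr = np.full(n, float(hr)) if np.isscalar(hr) else np.asarray(hr)
    return IntervalSeries(
        window_start=np.arange(n) * SEGMENT_SECONDS,
        hr_bpm=hr_arr, pq_ms=np.full(n, pq), qrs_ms=np.full(n, qrs),
        qt_ms=np.full(n, qt), beat_count=np.full(n, 12),
        usable=np.full(n, usable), start_time=start)


def mk_sdnn(start: datetime, hours: float, sdnn=35.0) -> SdnnSeries:
    n = int(hours * 12)
    return SdnnSeries(window_start=np.arange(n) * 300.0,
                      sdnn_ms=np.full(n, sdnn), nn_count=np.full(n, 300),
                      start_time=start)


NO_SYMPTOMS = pd.DataFrame(columns=["time_s", "type", "sources"])


# ---------------------------------------------------------------------------
# day windows
# ---------------------------------------------------------------------------

def test_day_windows_monday_10am_to_thursday_9am():
    """Recording Mon 10:00 - Thu 09:00: first full day is Mon-noon to
    Tue-noon, last full day Tue-noon to Wed-noon."""
    start = datetime(2024, 1, 1, 10, 0, 0)          # a Monday
    iv = mk_intervals(start, hours=71.0)
    first = select_day_window(iv, "first_full")
    last = select_day_window(iv, "last_full")
    assert first.start_time == datetime(2024, 1, 1, 12, 0, 0)
    assert last.start_time == datetime(2024, 1, 2, 12, 0, 0)
    assert first.end_s - first.start_s == 86400.0


def test_no_complete_day_raises():
    iv = mk_intervals(datetime(2024, 1, 1, 13, 0, 0), hours=22.0)
    with pytest.raises(ValueError):
        select_day_window(iv, "first_full")


def test_single_full_day_first_equals_last():
    iv = mk_intervals(datetime(2024, 1, 1, 11, 0, 0), hours=26.0)
    assert (select_day_window(iv, "first_full").start_s
            == select_day_window(iv, "last_full").start_s)


def test_mostly_unusable_day_disqualified():
    start = datetime(2024, 1, 1, 11, 0, 0)
    iv = mk_intervals(start, hours=50.0)
    # first noon-noon day only 40% usable; second day clean
    day0 = (iv.window_start >= 3600.0) & (iv.window_start < 3600.0 + 86400.0)
    idx = np.nonzero(day0)[0]
    iv.usable[idx[: int(0.6 * idx.size)]] = False
    w = select_day_window(iv, "first_full")
    assert w.start_s == pytest.approx(3600.0 + 86400.0)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_constant_hr_every_bin_70():
    start = datetime(2024, 1, 1, 11, 0, 0)
    iv = mk_intervals(start, hours=26.0)
    win = select_day_window(iv, "first_full")
    prof = circadian_profile(iv, mk_sdnn(start, 26.0), win)
    assert len(prof) == 8
    assert np.allclose(prof["hr_bpm"], 70.0)
    assert np.allclose(prof["qtc_ms"],
                       qtc_bazett(400.0, 60000.0 / 70.0))


def test_nocturnal_dip_lowest_bin():
    ps = generate_patient_series(default_cas_spec(seed=5))
    win = select_day_window(ps.intervals, "last_full")
    prof = circadian_profile(ps.intervals, ps.sdnn, win)
    hr = prof.set_index("bin")["hr_bpm"]
    assert hr.idxmin() == 1              # 3-6 AM bin (acrophase at 15:00)


def test_sparse_bin_absent():
    start = datetime(2024, 1, 1, 11, 0, 0)
    iv = mk_intervals(start, hours=26.0)
    win = select_day_window(iv, "first_full")
    # leave 5 usable windows in the 3-6 AM bin (clock 03:00 = t + 16 h)
    t0 = (27 - 11) * 3600.0
    m = (iv.window_start >= t0) & (iv.window_start < t0 + 3 * 3600.0)
    idx = np.nonzero(m)[0]
    iv.usable[idx[5:]] = False
    prof = circadian_profile(iv, mk_sdnn(start, 26.0), win)
    assert np.isnan(prof.loc[prof["bin"] == 1, "hr_bpm"].iloc[0])
    assert prof.loc[prof["bin"] == 1, "n_windows"].iloc[0] == 5


def test_bin_median_invariant_to_reordering():
    start = datetime(2024, 1, 1, 11, 0, 0)
    rng = np.random.default_rng(0)
    hr = rng.normal(70, 5, int(26 * 360))
    iv = mk_intervals(start, 26.0, hr=hr)
    win = select_day_window(iv, "first_full")
    p1 = circadian_profile(iv, mk_sdnn(start, 26.0), win)
    # shuffle values within one 3-h bin
    hours = iv.clock_hours()
    m = ((hours // 3).astype(int) % 8 == 2) & (iv.window_start >= win.start_s) \
        & (iv.window_start < win.end_s)
    vals = iv.hr_bpm[m]
    iv.hr_bpm[m] = vals[rng.permutation(vals.size)]
    p2 = circadian_profile(iv, mk_sdnn(start, 26.0), win)
    pd.testing.assert_frame_equal(p1, p2)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def test_identical_constant_groups_p_is_one():
    test, s, p = _two_group_test(np.full(9, 70.0), np.full(33, 70.0), 0.05)
    assert p == 1.0


def test_type_one_error_calibrated():
    """Under the null (both groups from one normal distribution), the
    Shapiro-gated Welch-t / Mann-Whitney choice rejects at ~5%."""
    rng = np.random.default_rng(11)
    rejections = 0
    n_rep = 2500
    for _ in range(n_rep):
        a = rng.normal(60, 6, 33)
        b = rng.normal(60, 6, 9)
        _, _, p = _two_group_test(a, b, 0.05)
        rejections += p < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.02)


def test_power_matches_normal_approximation():
    """5-bpm shift, SD 5, n = 33 vs 9: empirical power within Monte-Carlo
    error of the two-sample normal-approximation power."""
    delta, sd, n1, n2 = 5.0, 5.0, 33, 9
    se = sd * np.sqrt(1 / n1 + 1 / n2)
    power = 1 - stats.norm.cdf(1.96 - delta / se) \
        + stats.norm.cdf(-1.96 - delta / se)
    rng = np.random.default_rng(7)
    n_rep = 600
    hits = 0
    for _ in range(n_rep):
        a = rng.normal(60 + delta, sd, n1)
        b = rng.normal(60, sd, n2)
        _, _, p = _two_group_test(a, b, 0.05)
        hits += p < 0.05
    mc_se = np.sqrt(power * (1 - power) / n_rep)
    assert abs(hits / n_rep - power) < 4 * mc_se + 0.02


def test_compare_bins_structure():
    rng = np.random.default_rng(2)
    profiles, labels = [], []
    for i in range(12):
        rows = [{"bin": b, "hr_bpm": rng.normal(70, 5),
                 "pq_ms": rng.normal(160, 10), "qrs_ms": rng.normal(92, 3),
                 "qt_ms": rng.normal(400, 15), "qtc_ms": rng.normal(440, 15),
                 "sdnn_ms": rng.normal(35, 8)} for b in range(8)]
        profiles.append(pd.DataFrame(rows))
        labels.append(i < 8)
    out = compare_bins(profiles, labels)
    assert set(out["bin"]) == set(range(8))
    assert set(out["test"]) <= {"welch_t", "mannwhitney"}
    assert ((out["p"] >= 0) & (out["p"] <= 1)).all()


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_logistic_recovers_injected_log_odds():
    rng = np.random.default_rng(9)
    n = 2000
    x = rng.normal(0, 1, n)
    cov = pd.DataFrame({"age": rng.normal(60, 8, n),
                        "sex": rng.integers(0, 2, n),
                        "beta_blocker": rng.integers(0, 2, n),
                        "ccb": rng.integers(0, 2, n)})
    lin = -0.3 + 0.5 * x + 0.2 * cov["sex"].to_numpy()
    y = rng.random(n) < 1 / (1 + np.exp(-lin))
    res = adjusted_logistic(x, y, cov)
    assert res["adjusted"].flagged is None
    assert np.log(res["adjusted"].odds_ratio) == pytest.approx(0.5, abs=0.1)
    assert np.log(res["unadjusted"].odds_ratio) == pytest.approx(0.5, abs=0.12)


def test_logistic_null_ci_coverage():
    """Feature independent of label: the 95% Wald CI covers OR = 1 in about
    95% of replicates."""
    rng = np.random.default_rng(15)
    n_rep, covered = 200, 0
    for _ in range(n_rep):
        x = rng.normal(0, 1, 400)
        y = rng.random(400) < 0.4
        r = adjusted_logistic(x, y)["unadjusted"]
        if r.flagged is None and r.ci_low <= 1.0 <= r.ci_high:
            covered += 1
    assert 0.90 <= covered / n_rep <= 0.99


def test_logistic_flags_separation():
    x = np.concatenate([np.zeros(20), np.ones(20)])
    y = x > 0.5
    r = adjusted_logistic(x, y)["unadjusted"]
    assert r.flagged is not None
    assert r.odds_ratio is None


# ---------------------------------------------------------------------------
# resting 10 s and QTc
# ---------------------------------------------------------------------------

def test_resting_selection_argmin_and_tiebreak():
    start = datetime(2024, 1, 1, 10, 0, 0)
    iv = mk_intervals(start, hours=60.0, hr=60.0)
    # preferred day = Jan 2 (last window Jan 3 22:00 -> day prior = Jan 2)
    base = (datetime(2024, 1, 2, 6, 30) - start).total_seconds()
    iv.hr_bpm[:] = 60.0
    for off, hr in ((0.0, 71.0), (600.0, 74.8), (1200.0, 78.0)):
        iv.hr_bpm[int((base + off) // 10)] = hr
    r = select_resting_10s(iv, NO_SYMPTOMS)
    assert r.hr_bpm == pytest.approx(74.8)
    # exact ties: earliest window wins
    iv.hr_bpm[int(base // 10)] = 75.0
    iv.hr_bpm[int((base + 600) // 10)] = 75.0
    r2 = select_resting_10s(iv, NO_SYMPTOMS)
    assert r2.segment_start_s == pytest.approx(base)


def test_resting_fallback_to_second_prior_day():
    # recording Jan 1 04:00 - Jan 4 04:00: preferred morning Jan 3, fallback Jan 2
    start = datetime(2024, 1, 1, 4, 0, 0)
    iv = mk_intervals(start, hours=72.0, hr=74.0)
    base3 = (datetime(2024, 1, 3, 6, 30) - start).total_seconds()
    m = (iv.window_start >= base3) & (iv.window_start < base3 + 7200)
    iv.usable[m] = False                # preferred day band unusable
    r = select_resting_10s(iv, NO_SYMPTOMS)
    assert r is not None
    assert r.clock_time.day == 2


def test_resting_symptom_margin_excludes_windows():
    start = datetime(2024, 1, 1, 10, 0, 0)
    iv = mk_intervals(start, hours=60.0, hr=74.0)
    base = (datetime(2024, 1, 2, 6, 30) - start).total_seconds()
    sym = pd.DataFrame({"time_s": np.arange(base - 900, base + 7201, 1500.0),
                        "type": "chest_pain", "sources": "diary"})
    r = select_resting_10s(iv, sym)
    assert r is None or not (base <= r.segment_start_s < base + 7200)


@pytest.mark.parametrize("qt,rr,expect", [
    (400.0, 1000.0, 400.0),
    (405.0, 800.0, 452.8),
    (390.0, 1210.0, 354.5),
])
def test_qtc_bazett_closed_form(qt, rr, expect):
    assert qtc_bazett(qt, rr) == pytest.approx(expect, abs=0.05)


def test_qtc_errors_and_monotonicity():
    with pytest.raises(ValueError):
        qtc_bazett(400.0, 0.0)
    rr = np.linspace(600, 1400, 50)
    q = qtc_bazett(np.full(50, 400.0), rr)
    assert (np.diff(q) < 0).all()


def test_qtc_prolonged_convention():
    assert qtc_prolonged(461.0, "F") and not qtc_prolonged(459.0, "F")
    assert qtc_prolonged(451.0, "M") and not qtc_prolonged(449.0, "M")
    with pytest.raises(ValueError):
        qtc_prolonged(450.0, "X")
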