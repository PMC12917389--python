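"""Ischemia rule, burden normalisation, threshold sweep and symptom
concurrency."""

from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from conftest import make_spec
from holterkit import (DeviationSeries, LEADS, burden, detect_events,
                       merge_symptoms, patient_burden, symptom_concurrency,
                       threshold_sweep)
from holterkit.containers import SEGMENT_SECONDS
from holterkit.ischemia import IschemiaEvent
from holterkit.synthetic import (EpisodeSpec, generate_patient_series)
from oracles import brute_force_events

START = datetime(2024, 1, 1, 10, 0, 0)


def mk_dev(st, usable=None):
    st = np.asarray(st, float)
    n = st.shape[0]
    usable = np.ones(n, bool) if usable is None else np.asarray(usable, bool)
    stm = np.where(usable[:, None], st, np.nan)
    return DeviationSeries(segment_start=np.arange(n) * SEGMENT_SECONDS,
                           st=stm, tmin=stm * 0.5, tmax=stm * 0.5,
                           usable=usable,
                           baseline_bin=np.where(usable, 4, -1),
                           start_time=START)


def set_leads(n, lead_values):
    st = np.zeros((n, 12))
    for lead, (i0, i1, v) in lead_values.items():
        st[i0:i1, LEADS.index(lead)] = v
    return st


def test_zero_deviations_no_events():
    dev = mk_dev(np.zeros((100, 12)))
    assert detect_events(dev, "st_depression", 0.035) == []


def test_contiguous_pair_three_segments_is_one_event():
    st = set_leads(20, {"V4": (5, 8, -0.05), "V5": (5, 8, -0.05)})
    dev = mk_dev(st)
    evs = detect_events(dev, "st_depression", 0.035)
    assert len(evs) == 1
    ev = evs[0]
    assert ev.start_s == 50.0 and ev.end_s == 80.0
    assert ev.leads == ("V4", "V5")
    assert ev.duration_s >= 30.0


def test_single_lead_never_qualifies():
    st = set_leads(80, {"V2": (10, 70, -0.2)})
    dev = mk_dev(st)
    assert detect_events(dev, "st_depression", 0.035) == []


def test_two_segments_too_short():
    st = set_leads(20, {"V4": (5, 7, -0.05), "V5": (5, 7, -0.05)})
    assert detect_events(mk_dev(st), "st_depression", 0.035) == []


def test_unusable_segment_breaks_run():
    st = set_leads(20, {"V4": (5, 11, -0.05), "V5": (5, 11, -0.05)})
    usable = np.ones(20, bool)
    usable[8] = False
    evs = detect_events(mk_dev(st, usable), "st_depression", 0.035)
    assert [(e.start_s, e.end_s) for e in evs] == [(50.0, 80.0)]


def test_parameter_semantics():
    st = set_leads(20, {"V4": (5, 9, 0.05), "V5": (5, 9, 0.05)})
    dev = mk_dev(st)
    assert detect_events(dev, "st_depression", 0.035) == []
    assert len(detect_events(dev, "st_elevation", 0.035)) == 1
    assert len(detect_events(dev, "st_deviation", 0.035)) == 1
    with pytest.raises(ValueError):
        detect_events(dev, "st_magic", 0.035)
    with pytest.raises(ValueError):
        detect_events(dev, "st_depression", -0.1)


def test_non_adjacent_leads_do_not_pair():
    # II and V5 both exceed but are not contiguous
    st = set_leads(20, {"II": (5, 9, -0.05), "V5": (5, 9, -0.05)})
    assert detect_events(mk_dev(st), "st_depression", 0.035) == []


@pytest.mark.parametrize("total_s,usable_s,expect_norm,expect_flag", [
    (60.0, 86400.0, 60.0, True),
    (30.0, 43200.0, 60.0, True),
    (0.0, 86400.0, 0.0, False),
    (59.0, 86400.0, 59.0, False),
])
def test_burden_normalisation(total_s, usable_s, expect_norm, expect_flag):
    evs = ([IschemiaEvent("st_depression", 0.035, 0.0, total_s,
                          ("V4", "V5"), -0.05)] if total_s else [])
    b = burden(evs, usable_s)
    assert b.normalized_s_per_day == pytest.approx(expect_norm)
    assert b.flag_1min is expect_flag


def test_burden_requires_positive_usable():
    with pytest.raises(ValueError):
        burden([], 0.0)


def test_burden_additive_over_halves():
    rng = np.random.default_rng(5)
    st = rng.choice([0.0, -0.05], size=(200, 12), p=[0.7, 0.3])
    dev = mk_dev(st)
    total = sum(e.duration_s
                for e in detect_events(dev, "st_depression", 0.035))
    dev_a = mk_dev(st[:100])
    dev_b = mk_dev(st[100:])
    split = (sum(e.duration_s
                 for e in detect_events(dev_a, "st_depression", 0.035))
             + sum(e.duration_s
                   for e in detect_events(dev_b, "st_depression", 0.035)))
    # events crossing the split can only be lost, never created
    assert split <= total
    assert total - split <= 6 * SEGMENT_SECONDS


def test_events_match_brute_force_oracle():
    """Run-length event detection equals the exhaustive per-segment scanner
    on 500 randomised small deviation grids."""
    rng = np.random.default_rng(42)
    for rep in range(500):
        n = int(rng.integers(5, 40))
        st = rng.choice([0.0, -0.02, -0.05, 0.05, -0.2],
                        size=(n, 12), p=[0.55, 0.15, 0.15, 0.1, 0.05])
        usable = rng.random(n) > 0.1
        dev = mk_dev(st, usable)
        cutoff = float(rng.choice([0.01, 0.035, 0.04, 0.1]))
        param = str(rng.choice(["st_depression", "st_elevation",
                                "st_deviation"]))
        got = [(e.start_s, e.end_s)
               for e in detect_events(dev, param, cutoff)]
        want = brute_force_events(dev, param, cutoff)
        assert got == want, f"rep={rep} param={param} cutoff={cutoff}"


def test_sweep_flags_monotone_and_cutoff_zero():
    rng = np.random.default_rng(3)
    devs = []
    for _ in range(6):
        st = rng.normal(0, 0.02, (400, 12))
        st[50:80, LEADS.index("V4")] = -0.06
        st[50:80, LEADS.index("V5")] = -0.06
        devs.append(mk_dev(st))
    labels = [True, True, True, False, False, False]
    cutoffs = np.round(np.arange(0.0, 0.2001, 0.005), 6)
    sweep = threshold_sweep(devs, labels, "st_depression", cutoffs)
    # cutoff 0: any nonzero deviation in a contiguous pair for >=30 s
    assert sweep.flags[:, 0].all()
    diffs = np.diff(sweep.flags.astype(int), axis=1)
    assert (diffs <= 0).all()            # never false -> true with rising cutoff
    assert (np.diff(sweep.burdens, axis=1) <= 1e-9).all()


def test_end_to_end_recovery_low_noise():
    """Injected qualifying episodes are detected with sensitivity >= 0.95."""
    hits = tot = 0
    for seed in range(12):
        rng = np.random.default_rng(seed)
        eps = tuple(EpisodeSpec(
            kind="st_offset", amplitude_mv=-0.06, leads=("V4", "V5"),
            start_s=float(3000 + 8000 * k + rng.uniform(0, 500)),
            duration_s=120.0) for k in range(8))
        spec = make_spec(duration_days=1.0, fixed_episodes=eps,
                         st_noise_sd_mv=0.004, artifact_fraction=0.0,
                         daily_gap_minutes=0.0, seed=seed)
        ps = generate_patient_series(spec)
        evs = detect_events(ps.deviations, "st_depression", 0.035)
        for ep in eps:
            tot += 1
            if any(e.start_s <= ep.end_s and e.end_s >= ep.start_s
                   for e in evs):
                hits += 1
    assert hits / tot >= 0.95


# ---------------------------------------------------------------------------
# symptoms
# ---------------------------------------------------------------------------

def _log(rows):
    return pd.DataFrame(rows, columns=["patient_id", "source", "timestamp",
                                       "type", "duration_min"])


def test_merge_dedup_same_type_within_10min():
    t0 = START + timedelta(hours=1)
    log = _log([
        ("P0", "button", t0, "chest_pain", np.nan),
        ("P0", "diary", t0 + timedelta(minutes=4), "chest_pain", 10.0),
        ("P0", "diary", t0 + timedelta(minutes=30), "chest_pain", 5.0),
        ("P0", "button", t0 + timedelta(minutes=5), "fatigue", np.nan),
    ])
    merged = merge_symptoms(log, START)
    assert len(merged) == 3
    first = merged.iloc[0]
    assert first["sources"] == "button,diary"
    # diary timestamp kept for the merged symptom
    assert first["time_s"] == pytest.approx(3600 + 240)


def test_concurrency_boundary_inclusive():
    sym = pd.DataFrame({"time_s": [7200.0], "type": ["chest_pain"],
                        "sources": ["diary"]})
    ev_in = [IschemiaEvent("st_depression", 0.035, 7200 + 29 * 60,
                           7200 + 31 * 60, ("V4", "V5"), -0.05)]
    ev_out = [IschemiaEvent("st_depression", 0.035, 7200 - 40 * 60,
                            7200 - 31 * 60, ("V4", "V5"), -0.05)]
    ev_edge = [IschemiaEvent("st_depression", 0.035, 7200 - 40 * 60,
                             7200 - 30 * 60, ("V4", "V5"), -0.05)]
    assert symptom_concurrency(ev_in, sym).n_concurrent == 1
    assert symptom_concurrency(ev_out, sym).n_concurrent == 0
    assert symptom_concurrency(ev_edge, sym).n_concurrent == 1


def test_concurrency_percentage_and_no_symptom_patients():
    sym = pd.DataFrame({
        "time_s": [1000.0, 20000.0, 40000.0, 60000.0, 30000.0],
        "type": ["chest_pain", "dyspnea", "chest_pain", "dyspnea", "fatigue"],
        "sources": ["diary"] * 5})
    evs = [IschemiaEvent("st_depression", 0.035, 900.0, 1200.0,
                         ("V4", "V5"), -0.05)]
    r = symptom_concurrency(evs, sym)
    assert r.n_acute_symptoms == 4          # fatigue is not acute
    assert r.n_concurrent == 1
    assert r.pct_concurrent == pytest.approx(25.0)
    empty = symptom_concurrency(evs, sym.iloc[0:0])
    assert empty.pct_concurrent is None
    assert empty.flag_any_concurrent is False


def test_patient_burden_counts_only_usable_time():
    st = set_leads(30, {"V4": (0, 6, -0.05), "V5": (0, 6, -0.05)})
    usable = np.ones(30, bool)
    usable[20:] = False
    b = patient_burden(mk_dev(st, usable), "st_depression", 0.035)
    assert b.usable_s == pytest.approx(200.0)
    assert b.total_event_s == pytest.approx(60.0)
    assert b.normalized_s_per_day == pytest.approx(60.0 * 86400 / 200.0)
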