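"""Median beats, the heart-rate-matched baseline library and ST/T deviation
measurement."""

import numpy as np
import pytest

from conftest import make_spec
from holterkit import (LEADS, InsufficientBaselineError,
                       build_baseline_library, compute_median_beat,
                       segment_recording, st_deviation, t_wave_deviation)
from holterkit.config import DEFAULT_CONFIG
from holterkit.median_beat import BaselineBeat, BaselineLibrary, MedianBeat
from holterkit.synthetic import generate_recording


def _grid(fs=200.0):
    step = 1000.0 / fs
    return np.arange(-40, 91) * step   # -200 .. 452 ms around QRS onset


def _flat_beat(hr=60.0, qrs_ms=90.0, qt_ms=400.0, seg_start=0.0):
    t = _grid()
    return MedianBeat(segment_start=seg_start, t_ms=t,
                      waveform=np.zeros((t.size, 12)), hr_bpm=hr,
                      beat_count=12, qrs_ms=qrs_ms, qt_ms=qt_ms)


def _library_from(mb: MedianBeat) -> BaselineLibrary:
    lib = BaselineLibrary(t_ms=mb.t_ms)
    lib.bins[lib.bin_of(mb.hr_bpm)] = BaselineBeat(
        waveform=mb.waveform.copy(), n_segments=12,
        qrs_ms=mb.qrs_ms, qt_ms=mb.qt_ms)
    return lib


def test_median_of_identical_beats_is_the_beat(clean_segmented):
    rec, truth, beats, iv, sd, usable = clean_segmented
    seg = [b for b in beats if 100 <= b.r_time < 110]
    mb = compute_median_beat(rec, seg, 100.0)
    # extract one aligned beat directly
    on = int(round(seg[2].qrs_onset * rec.fs))
    rel = np.round(mb.t_ms * rec.fs / 1000.0).astype(int)
    one = rec.signal[on + rel, :]
    assert np.max(np.abs(mb.waveform - one)) < 1e-5


def test_median_suppresses_single_beat_spike(clean_recording):
    rec, truth = clean_recording
    rec2 = type(rec)(signal=rec.signal.copy(), fs=rec.fs, leads=rec.leads,
                     start_time=rec.start_time, gaps=[])
    i = int(103.0 * rec.fs)
    rec2.signal[i:i + 10, :] += 2.0      # artifact spike in one beat
    from holterkit.segmentation import detect_and_classify_beats
    beats = detect_and_classify_beats(rec2)
    seg = [b for b in beats if 100 <= b.r_time < 110]
    mb = compute_median_beat(rec2, seg, 100.0)
    clean = [b for b in beats if 110 <= b.r_time < 120]
    mb_clean = compute_median_beat(rec2, clean, 110.0)
    assert np.max(np.abs(mb.waveform - mb_clean.waveform)) < 0.01


def test_median_beat_needs_three_beats(clean_recording):
    rec, truth = clean_recording
    from holterkit.segmentation import detect_and_classify_beats
    beats = detect_and_classify_beats(rec)
    assert compute_median_beat(rec, beats[:2], 0.0) is None


def test_stationary_recording_single_bin_matches_template(clean_segmented):
    """Constant 60 bpm: one populated 57.5-62.5 bin whose baseline matches
    the generator template within 0.005 mV RMS."""
    rec, truth, beats, iv, sd, usable = clean_segmented
    from holterkit.median_beat import median_beats_by_segment
    mbs = median_beats_by_segment(rec, beats, usable)
    lib = build_baseline_library(mbs)
    assert list(lib.bins) == [4]         # bin centered at 60 bpm
    from holterkit.templates import MorphologyTemplate
    tpl = MorphologyTemplate(qrs_ms=92.0)
    rel, wave = tpl.render_beat(200.0, pq_ms=float(np.median(truth.beat_pq_ms)),
                                qt_ms=440.0)
    base = lib.bins[4].waveform
    t_idx = np.round(lib.t_ms * 0.2).astype(int)   # samples rel to QRS onset
    # the detected QRS onset may sit a sample or two off the template's; the
    # baseline shape itself must match within 0.005 mV RMS at the best shift
    best = np.inf
    for shift in range(-2, 3):
        m = (t_idx + shift >= rel) & (t_idx + shift < rel + wave.shape[0])
        rms = np.sqrt(np.mean((base[m] - wave[t_idx[m] + shift - rel]) ** 2))
        best = min(best, rms)
    assert best < 0.005


def test_hr_spread_populates_many_bins():
    mbs = []
    k = 0
    for hr in range(50, 101, 5):
        for _ in range(12):
            mbs.append(_flat_beat(hr=float(hr), seg_start=10.0 * k))
            k += 1
    lib = build_baseline_library(mbs)
    assert len(lib.bins) >= 8


def test_insufficient_baseline_raises():
    spec = make_spec(duration_days=30 / 86400.0, seed=2)
    rec, truth = generate_recording(spec)
    beats, iv, sd, usable = segment_recording(rec)
    from holterkit.median_beat import median_beats_by_segment
    mbs = median_beats_by_segment(rec, beats, usable)
    with pytest.raises(InsufficientBaselineError):
        build_baseline_library(mbs)


def test_identical_beats_zero_deviation():
    mb = _flat_beat()
    mb.waveform[:, :] = 0.1 * np.sin(mb.t_ms / 50.0)[:, None]
    lib = _library_from(mb)
    dev, b = st_deviation(mb, lib)
    mn, mx, _ = t_wave_deviation(mb, lib)
    assert np.allclose(dev, 0.0, atol=1e-12)
    assert np.allclose(mn, 0.0, atol=1e-12) and np.allclose(mx, 0.0, atol=1e-12)


def test_constructed_st_shift_measured_exactly():
    """Baseline flat at 0; segment ST window shifted -0.05 mV in V5 only."""
    base = _flat_beat()
    lib = _library_from(base)
    seg = _flat_beat()
    seg.waveform = seg.waveform.copy()
    j5 = LEADS.index("V5")
    st = (seg.t_ms >= seg.qrs_ms) & (seg.t_ms <= seg.qrs_ms + 120)
    seg.waveform[st, j5] = -0.05
    dev, b = st_deviation(seg, lib)
    assert dev[j5] == pytest.approx(-0.05, abs=1e-12)
    others = np.delete(dev, j5)
    assert np.allclose(others, 0.0, atol=1e-12)


def _with_t_wave(amp_by_lead):
    mb = _flat_beat()
    w = mb.waveform.copy()
    t_on, t_off = mb.qrs_ms + 80.0, mb.qt_ms
    m = (mb.t_ms >= t_on) & (mb.t_ms <= t_off)
    shape = np.sin(np.pi * (mb.t_ms[m] - t_on) / (t_off - t_on))
    for lead, amp in amp_by_lead.items():
        w[m, LEADS.index(lead)] = amp * shape
    mb.waveform = w
    return mb


def test_t_amplitude_halved_gives_minus_015():
    base = _with_t_wave({"V5": 0.30})
    seg = _with_t_wave({"V5": 0.15})
    lib = _library_from(base)
    mn, mx, _ = t_wave_deviation(seg, lib)
    assert mx[LEADS.index("V5")] == pytest.approx(-0.15, abs=1e-9)


def test_biphasic_t_inversion_deviations():
    """Inverting an asymmetric biphasic T (+0.3 then -0.1 lobes): the min-T
    deviation is -(max+|min|) = -0.2 mV and the max-T deviation +0.2 mV."""
    base = _flat_beat()
    seg = _flat_beat()
    m = (base.t_ms >= base.qrs_ms + 80) & (base.t_ms <= base.qt_ms)
    x = np.linspace(0, 2 * np.pi, m.sum())
    bi = np.where(np.sin(x) >= 0, 0.3 * np.sin(x), 0.1 * np.sin(x))
    j = LEADS.index("V3")
    base.waveform = base.waveform.copy()
    seg.waveform = seg.waveform.copy()
    base.waveform[m, j] = bi
    seg.waveform[m, j] = -bi
    lib = _library_from(base)
    mn, mx, _ = t_wave_deviation(seg, lib)
    assert mn[j] == pytest.approx(float((-bi).min() - bi.min()), abs=1e-9)
    assert mx[j] == pytest.approx(float((-bi).max() - bi.max()), abs=1e-9)
    assert mn[j] == pytest.approx(-0.2, abs=1e-2)
    assert mx[j] == pytest.approx(-0.2, abs=1e-2)


def test_deviation_antisymmetry():
    rng = np.random.default_rng(0)
    a = _flat_beat()
    b = _flat_beat()
    a.waveform = rng.normal(0, 0.1, a.waveform.shape)
    b.waveform = rng.normal(0, 0.1, b.waveform.shape)
    lib_b = _library_from(b)
    lib_a = _library_from(a)
    d_ab, _ = st_deviation(a, lib_b)
    d_ba, _ = st_deviation(b, lib_a)
    assert np.allclose(d_ab, -d_ba, atol=1e-12)
    mn_ab, mx_ab, _ = t_wave_deviation(a, lib_b)
    mn_ba, mx_ba, _ = t_wave_deviation(b, lib_a)
    assert np.allclose(mn_ab, -mn_ba, atol=1e-12)
    assert np.allclose(mx_ab, -mx_ba, atol=1e-12)


def test_hr_matching_limited_to_10_bpm():
    base = _flat_beat(hr=60.0)
    lib = _library_from(base)
    near = _flat_beat(hr=68.0)
    far = _flat_beat(hr=75.0)
    dev_near, b_near = st_deviation(near, lib)
    dev_far, b_far = st_deviation(far, lib)
    assert dev_near is not None and b_near == lib.bin_of(60.0)
    assert dev_far is None and b_far == -1


def test_null_calibration_no_episode(episode_deviations):
    """Away from the injected episode, ST deviations center on zero."""
    rec, truth, dev = episode_deviations
    outside = (dev.segment_start < 850) | (dev.segment_start > 1080)
    vals = dev.st[outside]
    assert abs(np.nanmean(vals)) < 0.005


def test_injected_episode_recovered(episode_deviations):
    """-0.05 mV ST offset in V4/V5 reconstructed to within 0.005 mV by the
    full waveform -> median-beat -> deviation chain."""
    rec, truth, dev = episode_deviations
    j4, j5 = LEADS.index("V4"), LEADS.index("V5")
    inside = (dev.segment_start >= 920) & (dev.segment_start < 1000)
    assert np.nanmean(dev.st[inside, j4]) == pytest.approx(-0.05, abs=0.005)
    assert np.nanmean(dev.st[inside, j5]) == pytest.approx(-0.05, abs=0.005)
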