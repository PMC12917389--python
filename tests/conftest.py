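import numpy as np
import pytest

from holterkit import segment_recording
from holterkit.synthetic import EpisodeSpec, PatientSpec, generate_recording


def make_spec(**kw) -> PatientSpec:
    """Short waveform-tier spec with quiet defaults; override per test."""
    base = dict(
        group="CAS", duration_days=600 / 86400.0, allow_any_duration=True,
        hr_mesor_bpm=60.0, hr_amplitude_bpm=0.0, rr_jitter_ms=0.0,
        noise_rms_mv=0.0, artifact_fraction=0.0, daily_gap_minutes=0.0,
        ischemia_prone_prob=0.0, ectopic_prob=0.0, seed=3,
    )
    base.update(kw)
    return PatientSpec(**base)


@pytest.fixture(scope="session")
def clean_recording():
    """10 min at a constant 60 bpm, no noise, no episodes."""
    return generate_recording(make_spec())


@pytest.fixture(scope="session")
def clean_segmented(clean_recording):
    rec, truth = clean_recording
    beats, iv, sd, usable = segment_recording(rec)
    return rec, truth, beats, iv, sd, usable


@pytest.fixture(scope="session")
def episode_recording():
    """30 min, mild noise and RR jitter, one 120-s ST-depression episode of
    -0.05 mV in V4/V5."""
    ep = EpisodeSpec(kind="st_offset", amplitude_mv=-0.05,
                     leads=("V4", "V5"), start_s=900.0, duration_s=120.0,
                     ramp_s=10.0)
    spec = make_spec(duration_days=1800 / 86400.0, rr_jitter_ms=10.0,
                     noise_rms_mv=0.01, fixed_episodes=(ep,), seed=5)
    return generate_recording(spec)


@pytest.fixture(scope="session")
def episode_deviations(episode_recording):
    from holterkit import (build_baseline_library, deviation_series,
                           median_beats_by_segment)
    rec, truth = episode_recording
    beats, iv, sd, usable = segment_recording(rec)
    mbs = median_beats_by_segment(rec, beats, usable)
    lib = build_baseline_library(mbs)
    dev = deviation_series(mbs, lib, usable, start_time=rec.start_time)
    return rec, truth, dev
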