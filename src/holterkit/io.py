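"""Readers and writers.

The native interchange for recordings is a plain-text pair: a JSON header
(``<stem>.header.json``: sampling rate, lead labels, start time, gaps) plus a
CSV waveform (``<stem>.csv``, one column per lead, mV).  EDF files can be
read when :mod:`mne` is installed.  Channel labels are normalised to the 12
standard lead names; unmapped labels raise with the offending labels listed.

Per-10-s series, symptom logs and events travel as tidy CSV; ground truth as
JSON.  Every table written through :func:`save_table` carries the config hash
as a comment line for provenance.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .containers import DeviationSeries, EcgRecording, IntervalSeries, SdnnSeries
from .leads import normalize_lead

ISO = "%Y-%m-%dT%H:%M:%S"


def write_recording(rec: EcgRecording, stem: str | Path,
                    decimals: int = 4) -> tuple[Path, Path]:
    """Write a recording as ``<stem>.header.json`` + ``<stem>.csv``."""
    stem = Path(stem)
    header = {
        "fs": rec.fs,
        "leads": list(rec.leads),
        "start_time": rec.start_time.strftime(ISO),
        "gaps": [list(g) for g in rec.gaps],
        "n_samples": int(rec.n_samples),
        "units": "mV",
    }
    hpath = stem.with_suffix(".header.json")
    cpath = stem.with_suffix(".csv")
    hpath.write_text(json.dumps(header, indent=1))
    pd.DataFrame(np.round(rec.signal, decimals), columns=list(rec.leads)
                 ).to_csv(cpath, index=False)
    return hpath, cpath


def _read_native(stem: Path) -> EcgRecording:
    header = json.loads(stem.with_suffix(".header.json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"))
    leads = [normalize_lead(l) for l in header["leads"]]
    bad = [c for c in df.columns if c not in leads]
    if bad:
        raise ValueError(f"unmapped ECG channel label(s): {bad}")
    return EcgRecording(
        signal=df[leads].to_numpy(np.float32), fs=float(header["fs"]),
        leads=tuple(leads),
        start_time=datetime.strptime(header["start_time"], ISO),
        gaps=[tuple(g) for g in header.get("gaps", [])])


def _read_edf(path: Path) -> EcgRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    bad = []
    leads = []
    for name in raw.ch_names:
        try:
            leads.append(normalize_lead(name))
        except ValueError:
            bad.append(name)
    if bad:
        raise ValueError(f"unmapped ECG channel label(s): {bad}")
    sig = raw.get_data().T * 1000.0  # volts -> mV
    meas = raw.info.get("meas_date")
    start = (meas.replace(tzinfo=None) if meas is not None
             else datetime(2024, 1, 1, 10, 0, 0))
    return EcgRecording(signal=sig.astype(np.float32),
                        fs=float(raw.info["sfreq"]), leads=tuple(leads),
                        start_time=start)


def read_recording(path: str | Path, format: str = "auto",
                   gap_sidecar: Optional[str | Path] = None) -> EcgRecording:
    """Read a recording (native text format or EDF).

    A sidecar JSON of gap intervals (``[[start_s, end_s], ...]``) is applied
    on top of the header's own gaps when provided.
    """
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "native"
    if format == "native":
        stem = path.with_suffix("") if path.suffix else path
        if str(stem).endswith(".header"):
            stem = Path(str(stem)[: -len(".header")])
        rec = _read_native(stem)
    elif format == "edf":
        rec = _read_edf(path)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if gap_sidecar is not None:
        extra = json.loads(Path(gap_sidecar).read_text())
        gaps = sorted(list(rec.gaps) + [tuple(g) for g in extra])
        rec = EcgRecording(signal=rec.signal, fs=rec.fs, leads=rec.leads,
                           start_time=rec.start_time, gaps=gaps)
    return rec


# ---------------------------------------------------------------------------
# tables and logs
# ---------------------------------------------------------------------------

def save_table(df: pd.DataFrame, path: str | Path,
               config: PipelineConfig = DEFAULT_CONFIG) -> Path:
    """CSV with a provenance comment line (config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.hash()}\n")
        df.to_csv(fh, index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_symptom_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = log.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(ISO)
    out.to_csv(path, index=False)
    return path


def read_symptom_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_ground_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def write_interval_series(iv: IntervalSeries, path: str | Path,
                          config: PipelineConfig = DEFAULT_CONFIG) -> Path:
    return save_table(iv.to_frame(), path, config)


def read_interval_series(path: str | Path, start_time=None) -> IntervalSeries:
    df = load_table(path)
    kwargs = {} if start_time is None else {"start_time": start_time}
    return IntervalSeries.from_frame(df, **kwargs)


def write_deviation_series(dev: DeviationSeries, path: str | Path,
                           config: PipelineConfig = DEFAULT_CONFIG) -> Path:
    return save_table(dev.to_frame(), path, config)


def read_deviation_series(path: str | Path, start_time=None) -> DeviationSeries:
    df = load_table(path)
    kwargs = {} if start_time is None else {"start_time": start_time}
    return DeviationSeries.from_frame(df, **kwargs)
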