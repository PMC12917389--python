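"""End-to-end cohort analysis: ties the modules together and writes tidy
artifacts.  Used by the command-line interface and the worked examples."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import circadian as circ
from . import diagnostics as dx
from . import io as hio
from . import ischemia as isch
from .config import DEFAULT_CONFIG, PipelineConfig
from .synthetic import PatientSeries, generate_cohort

log = logging.getLogger(__name__)

HEADLINE_CUTOFFS = (0.035, 0.040)


@dataclass
class CohortAnalysis:
    sweep_curves: pd.DataFrame
    accuracy: pd.DataFrame          # per cutoff/criterion: sens/spec/ppv/npv
    auc: pd.DataFrame
    concurrency: pd.DataFrame
    circadian_group: pd.DataFrame
    circadian_tests: pd.DataFrame
    resting: pd.DataFrame
    config_hash: str = ""

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "sweep_curves": self.sweep_curves,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "concurrency": self.concurrency,
            "circadian_group": self.circadian_group,
            "circadian_tests": self.circadian_tests,
            "resting": self.resting,
        }

    def digest(self) -> str:
        """Bit-stable digest over all result tables (determinism check)."""
        h = hashlib.sha256()
        for name, df in sorted(self.tables().items()):
            h.update(name.encode())
            h.update(df.round(9).to_csv(index=False).encode())
        return h.hexdigest()

    def save(self, outdir: str | Path,
             config: PipelineConfig = DEFAULT_CONFIG) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            hio.save_table(df, outdir / f"{name}.csv", config)
        (outdir / "digest.json").write_text(json.dumps(
            {"digest": self.digest(), "config_hash": config.hash()}, indent=1))


def _metric_rows(t: dx.TwoByTwo, criterion: str, cutoff: float,
                 ) -> list[dict]:
    rows = []
    p = dx.fisher_exact(t)
    for name, m in dx.metrics(t).items():
        rows.append({"criterion": criterion, "cutoff_mv": cutoff,
                     "metric": name, "estimate": m.estimate,
                     "ci_low": m.ci_low, "ci_high": m.ci_high,
                     "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
                     "fisher_p": p})
    return rows


def analyze_cohort(cohort: Sequence[PatientSeries],
                   config: PipelineConfig = DEFAULT_CONFIG,
                   seed: int = 0,
                   parameter: str = "st_depression",
                   sweep_cutoffs: Optional[np.ndarray] = None,
                   ) -> CohortAnalysis:
    """Run the full analysis over a cohort of per-patient series bundles."""
    labels = np.array([p.label == "CAS" for p in cohort])
    deviations = [p.deviations for p in cohort]
    ids = [p.patient_id for p in cohort]

    sweep = isch.threshold_sweep(deviations, labels, parameter=parameter,
                                 cutoffs_mv=sweep_cutoffs, config=config,
                                 patient_ids=ids)
    sweep_curves = dx.assemble_sweep_curves(sweep, config)

    # headline cutoffs: burden flags, concurrency flags, accuracy metrics
    acc_rows: list[dict] = []
    conc_rows: list[dict] = []
    auc_rows: list[dict] = []
    for cut in HEADLINE_CUTOFFS:
        flags, burdens, conc_flags = [], [], []
        for p in cohort:
            bs = isch.patient_burden(p.deviations, parameter, cut, config)
            flags.append(bs.flag_1min)
            burdens.append(bs.normalized_s_per_day)
            events = isch.detect_events(p.deviations, parameter, cut, config)
            merged = isch.merge_symptoms(p.symptoms, p.spec.start_time, config)
            cr = isch.symptom_concurrency(events, merged, cut, config)
            conc_flags.append(cr.flag_any_concurrent)
            conc_rows.append({
                "patient_id": p.patient_id, "label": p.label,
                "cutoff_mv": cut, "n_acute_symptoms": cr.n_acute_symptoms,
                "n_concurrent": cr.n_concurrent,
                "pct_concurrent": cr.pct_concurrent,
                "flag_any_concurrent": cr.flag_any_concurrent})
        t_burden = dx.two_by_two(flags, labels,
                                 rule=f">=1 min/day {parameter} >= {cut} mV")
        acc_rows += _metric_rows(t_burden, "burden_1min_daily", cut)
        t_conc = dx.two_by_two(conc_flags, labels,
                               rule=f">=1 symptom concurrent @ {cut} mV")
        acc_rows += _metric_rows(t_conc, "symptom_concurrent", cut)

        score = (np.asarray(burdens, float) if config.auc_score == "burden"
                 else np.asarray(flags, float))
        if labels.any() and (~labels).any():
            roc = dx.roc_auc_bootstrap(score, labels,
                                       n_bootstrap=config.bootstrap_samples,
                                       seed=seed,
                                       stratified=config.bootstrap_stratified)
            auc_rows.append({"criterion": "burden_score", "cutoff_mv": cut,
                             "auc": roc.auc, "ci_low": roc.ci_low,
                             "ci_high": roc.ci_high,
                             "n_bootstrap": roc.n_bootstrap})
            roc_c = dx.roc_auc_bootstrap(np.asarray(conc_flags, float),
                                         labels,
                                         n_bootstrap=config.bootstrap_samples,
                                         seed=seed,
                                         stratified=config.bootstrap_stratified)
            auc_rows.append({"criterion": "symptom_concurrent_flag",
                             "cutoff_mv": cut, "auc": roc_c.auc,
                             "ci_low": roc_c.ci_low, "ci_high": roc_c.ci_high,
                             "n_bootstrap": roc_c.n_bootstrap})

    # circadian: last full day
    profiles, kept = [], []
    resting_rows: list[dict] = []
    for p in cohort:
        try:
            win = circ.select_day_window(p.intervals, "last_full", config)
        except ValueError:
            continue
        profiles.append(circ.circadian_profile(p.intervals, p.sdnn, win,
                                               config))
        kept.append(p.label == "CAS")
        merged = isch.merge_symptoms(p.symptoms, p.spec.start_time, config)
        r = circ.select_resting_10s(p.intervals, merged, config=config)
        if r is not None:
            resting_rows.append({
                "patient_id": p.patient_id, "label": p.label,
                "hr_bpm": r.hr_bpm, "pq_ms": r.pq_ms, "qrs_ms": r.qrs_ms,
                "qt_ms": r.qt_ms, "qtc_ms": r.qtc_ms,
                "segment_start_s": r.segment_start_s})
    circadian_group = (circ.group_profile(profiles, kept)
                       if profiles else pd.DataFrame())
    circadian_tests = (circ.compare_bins(profiles, kept)
                       if len(profiles) >= 4 else pd.DataFrame())

    return CohortAnalysis(
        sweep_curves=sweep_curves,
        accuracy=pd.DataFrame(acc_rows),
        auc=pd.DataFrame(auc_rows),
        concurrency=pd.DataFrame(conc_rows),
        circadian_group=circadian_group,
        circadian_tests=circadian_tests,
        resting=pd.DataFrame(resting_rows),
        config_hash=config.hash())


def fixture_cohort(seed: int = 11, n_cas: int = 4, n_nocas: int = 2,
                   duration_days: float = 3.0) -> list[PatientSeries]:
    """The packaged small demonstration cohort (series tier)."""
    from .synthetic import default_cas_spec, default_nocas_spec
    from dataclasses import replace
    cas = default_cas_spec(duration_days=duration_days)
    nocas = default_nocas_spec(duration_days=duration_days)
    return generate_cohort(n_cas, n_nocas, cas, nocas, seed=seed)


def run_fixture_pipeline(seed: int = 11, outdir: Optional[str | Path] = None,
                         config: PipelineConfig = DEFAULT_CONFIG,
                         sweep_step_mv: float = 0.025,
                         ) -> CohortAnalysis:
    """Simulate the fixture cohort and run the full analysis (coarse sweep
    grid by default to keep the demonstration fast)."""
    cohort = fixture_cohort(seed=seed)
    cutoffs = np.round(np.arange(0.0, 0.5 + 1e-9, sweep_step_mv), 6)
    result = analyze_cohort(cohort, config=config, seed=seed,
                            sweep_cutoffs=cutoffs)
    if outdir is not None:
        result.save(outdir, config)
    return result
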