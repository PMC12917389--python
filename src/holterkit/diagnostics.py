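"""Diagnostic-accuracy layer: 2x2 tables with Wilson-interval metrics,
Fisher exact tests, bootstrap ROC/AUC, and threshold-sweep curve assembly.

All proportions carry 95% Wilson score intervals; AUC confidence intervals
come from percentile bootstrap (1000 stratified resamples by default).  Tests
are two-sided at alpha = 0.05 and no multiple-testing correction is applied
(the analysis is exploratory; output metadata flags this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, PipelineConfig
from .ischemia import SweepResult


@dataclass
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int
    rule: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate + 1e-12
                and self.estimate - 1e-12 <= self.ci_high <= 1.0):
            raise ValueError("CI must bracket the estimate within [0, 1]")


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: pd.DataFrame            # threshold, sensitivity, one_minus_spec
    n_bootstrap: int
    seed: int


def wilson_ci(successes: int, n: int, conf: float = 0.95,
              ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == n else min(1.0, center + half)
    return lo, hi


def two_by_two(flags: Sequence[bool], labels: Sequence[bool],
               rule: str = "") -> TwoByTwo:
    """Cross-tabulate positivity flags against disease labels.

    Patients with no symptoms enter symptom-concurrency tables with a false
    flag, so flags and labels must already be aligned one per patient.
    """
    flags = np.asarray(flags, bool)
    labels = np.asarray(labels, bool)
    if flags.size == 0 or flags.shape != labels.shape:
        raise ValueError("flags and labels must be aligned and non-empty")
    return TwoByTwo(tp=int(np.sum(flags & labels)),
                    fp=int(np.sum(flags & ~labels)),
                    fn=int(np.sum(~flags & labels)),
                    tn=int(np.sum(~flags & ~labels)),
                    rule=rule)


def metrics(t: TwoByTwo, conf: float = 0.95) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV and NPV with Wilson intervals.

    Metrics with a zero denominator are absent from the result.
    """
    out: dict[str, MetricWithCI] = {}
    pairs = {
        "sensitivity": (t.tp, t.tp + t.fn),
        "specificity": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
    }
    for name, (k, n) in pairs.items():
        if n == 0:
            continue
        lo, hi = wilson_ci(k, n, conf)
        out[name] = MetricWithCI(estimate=k / n, ci_low=lo, ci_high=hi)
    return out


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities not
    exceeding that of the observed table)."""
    _, p = stats.fisher_exact([[t.tp, t.fp], [t.fn, t.tn]],
                              alternative="two-sided")
    return float(p)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with 0.5 credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc_bootstrap(scores: Sequence[float], labels: Sequence[bool],
                      n_bootstrap: int = 1000, seed: int = 0,
                      stratified: bool = True,
                      ) -> RocResult:
    """AUC with a percentile bootstrap CI (resampling with replacement,
    stratified by group by default to preserve the class imbalance)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    auc = rank_auc(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.nonzero(labels)[0]
    neg = np.nonzero(~labels)[0]
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        if stratified:
            idx = np.concatenate([rng.choice(pos, pos.size, replace=True),
                                  rng.choice(neg, neg.size, replace=True)])
        else:
            while True:
                idx = rng.choice(labels.size, labels.size, replace=True)
                if labels[idx].any() and (~labels[idx]).any():
                    break
        boots[b] = rank_auc(scores[idx], labels[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])

    thresholds = np.unique(scores)[::-1]
    rows = [{"threshold": np.inf, "sensitivity": 0.0, "one_minus_spec": 0.0}]
    n1, n0 = labels.sum(), (~labels).sum()
    for th in thresholds:
        pred = scores >= th
        rows.append({"threshold": float(th),
                     "sensitivity": float((pred & labels).sum() / n1),
                     "one_minus_spec": float((pred & ~labels).sum() / n0)})
    return RocResult(auc=auc, ci_low=float(lo), ci_high=float(hi),
                     curve=pd.DataFrame(rows), n_bootstrap=n_bootstrap,
                     seed=seed)


# ---------------------------------------------------------------------------
# sweep curves
# ---------------------------------------------------------------------------

def sweep_proportions(sweep: SweepResult,
                      config: PipelineConfig = DEFAULT_CONFIG,
                      ) -> pd.DataFrame:
    """Per-cutoff positive proportions per group with Wilson bands and Fisher
    p, ready for plotting (the exploratory threshold-sweep figure)."""
    rows = []
    labels = sweep.labels
    for c, cut in enumerate(sweep.cutoffs_mv):
        fl = sweep.flags[:, c]
        t = two_by_two(fl, labels)
        p = fisher_exact(t)
        for grp, name in ((True, "CAS"), (False, "no_CAS")):
            k = int(fl[labels == grp].sum())
            n = int((labels == grp).sum())
            lo, hi = wilson_ci(k, n)
            rows.append({"parameter": sweep.parameter,
                         "cutoff_mv": float(cut), "group": name,
                         "n_pos": k, "n": n, "prop": k / n,
                         "wilson_lo": lo, "wilson_hi": hi,
                         "fisher_p": p,
                         "significant": p < config.alpha,
                         "covadis_reference":
                             abs(cut - config.covadis_reference_mv) < 1e-9})
    return pd.DataFrame(rows)


def assemble_sweep_curves(sweep: SweepResult,
                          config: PipelineConfig = DEFAULT_CONFIG,
                          ) -> pd.DataFrame:
    """Alias with the tidy-output contract; see :func:`sweep_proportions`."""
    df = sweep_proportions(sweep, config)
    df.attrs["multiple_testing_correction"] = "none (exploratory analysis)"
    df.attrs["alpha"] = config.alpha
    return df
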