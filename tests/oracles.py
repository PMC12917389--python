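"""Independent brute-force oracles used only by the tests."""

from __future__ import annotations

import math

import numpy as np

from holterkit.containers import DeviationSeries, SEGMENT_SECONDS
from holterkit.leads import CONTIGUOUS_PAIRS, LEAD_INDEX


def brute_force_events(dev: DeviationSeries, parameter: str, cutoff: float,
                       min_seg: int = 3) -> list[tuple[float, float]]:
    """Event intervals by exhaustive scanning straight from the rule
    definition: a segment t qualifies iff some contiguous pair and some run
    [a, b) containing t of length >= min_seg has both leads exceeding in
    every segment of the run; events are maximal qualifying runs.

    O(pairs * n^2) on purpose - no run-length shortcuts.
    """
    x = dev.measure(parameter)
    n = x.shape[0]
    with np.errstate(invalid="ignore"):
        if parameter == "st_depression":
            exceed = x <= -cutoff
        elif parameter == "st_elevation":
            exceed = x >= cutoff
        else:
            exceed = np.abs(x) >= cutoff
    exceed &= dev.usable[:, None]

    qualifying = np.zeros(n, bool)
    for (la, lb) in CONTIGUOUS_PAIRS:
        i, j = LEAD_INDEX[la], LEAD_INDEX[lb]
        both = exceed[:, i] & exceed[:, j]
        for a in range(n):
            for b in range(a + min_seg, n + 1):
                if all(both[a:b]):
                    qualifying[a:b] = True
                else:
                    break
    events = []
    t = 0
    while t < n:
        if qualifying[t]:
            a = t
            while t < n and qualifying[t]:
                t += 1
            events.append((float(dev.segment_start[a]),
                           float(dev.segment_start[t - 1] + SEGMENT_SECONDS)))
        else:
            t += 1
    return events


def fisher_enumeration(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration over the
    hypergeometric support with fixed margins."""
    r1, r2 = tp + fp, fn + tn
    c1 = tp + fn
    n = r1 + r2

    def log_hyper(a: int) -> float:
        # P(table with top-left = a | margins)
        return (math.lgamma(r1 + 1) - math.lgamma(a + 1)
                - math.lgamma(r1 - a + 1)
                + math.lgamma(r2 + 1) - math.lgamma(c1 - a + 1)
                - math.lgamma(r2 - (c1 - a) + 1)
                - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                   - math.lgamma(n - c1 + 1)))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    probs = {a: math.exp(log_hyper(a)) for a in range(lo, hi + 1)}
    p_obs = probs[tp]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-10)))


def wilson_closed_form(k: int, n: int, z: float = 1.959963984540054,
                       ) -> tuple[float, float]:
    """Wilson score interval evaluated directly from its closed form."""
    p = k / n
    center = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = (z / (1 + z * z / n)) * math.sqrt(
        p * (1 - p) / n + z * z / (4 * n * n))
    return center - half, center + half
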