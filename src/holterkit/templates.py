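"""Parametric single-beat morphology used by the synthetic Holter generator.

A beat is composed of compact-support waves: a triangular P wave, a QRS
complex built from three raised-cosine deflections (Q, R, S), and a T wave
with a raised-cosine upstroke and a linear downstroke.  Compact support makes
the generator's fiducial ground truth exact: each wave starts and ends at its
nominal onset/offset, and the PQ segment is isoelectric at 0 mV.

Per-lead appearance is a scaling of the same shapes by lead factors, which is
sufficient for a pipeline that only consumes fiducials, ST windows and T
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leads import LEADS

# (P, QRS, T) scale factors per lead; roughly typical adult relative
# amplitudes, with negative QRS/T in aVR and V1.
DEFAULT_LEAD_FACTORS: dict[str, tuple[float, float, float]] = {
    "I":   (0.60, 0.55, 0.50),
    "II":  (1.00, 1.00, 1.00),
    "III": (0.50, 0.45, 0.50),
    "aVR": (-0.80, -0.75, -0.75),
    "aVL": (0.20, 0.20, 0.20),
    "aVF": (0.75, 0.70, 0.75),
    "V1":  (0.30, -0.40, -0.30),
    "V2":  (0.40, 0.60, 0.80),
    "V3":  (0.50, 0.90, 1.10),
    "V4":  (0.60, 1.20, 1.00),
    "V5":  (0.70, 1.10, 0.90),
    "V6":  (0.70, 0.90, 0.70),
}


def _hann_bump(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """Raised-cosine bump with support [a, b], unit peak."""
    out = np.zeros_like(t)
    m = (t >= a) & (t <= b)
    if b > a:
        out[m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[m] - a) / (b - a)))
    return out


def _triangle(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """Unit-peak symmetric triangle with support [a, b]."""
    out = np.zeros_like(t)
    mid = 0.5 * (a + b)
    m1 = (t >= a) & (t <= mid)
    m2 = (t > mid) & (t <= b)
    if mid > a:
        out[m1] = (t[m1] - a) / (mid - a)
    if b > mid:
        out[m2] = (b - t[m2]) / (b - mid)
    return out


@dataclass
class MorphologyTemplate:
    """Per-patient beat morphology with exact fiducial offsets.

    Reference intervals are at the template's reference RR; the generator
    overrides PQ and QT beat by beat from the circadian models.
    """

    p_amp_mv: float = 0.12
    r_amp_mv: float = 1.0
    q_rel: float = -0.08          # Q amplitude relative to R
    s_rel: float = -0.20          # S amplitude relative to R
    t_amp_mv: float = 0.30
    p_duration_ms: float = 110.0
    pq_ms: float = 160.0          # P onset -> QRS onset
    qrs_ms: float = 90.0
    qt_ms: float = 400.0          # QRS onset -> T offset
    rr_ref_ms: float = 1000.0
    lead_factors: dict = field(
        default_factory=lambda: dict(DEFAULT_LEAD_FACTORS))

    def __post_init__(self) -> None:
        f = self.fiducials_ms()
        seq = [f["p_onset"], f["p_offset"], f["qrs_onset"],
               f["qrs_offset"], f["t_offset"]]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("template fiducial offsets must be increasing")
        peak = max(abs(self.r_amp_mv), abs(self.p_amp_mv), abs(self.t_amp_mv))
        if peak * max(abs(v) for fac in self.lead_factors.values()
                      for v in fac) > 5.0:
            raise ValueError("template amplitude exceeds 5 mV")

    def fiducials_ms(self, pq_ms: float | None = None,
                     qt_ms: float | None = None) -> dict[str, float]:
        """Fiducial offsets within the template, ms from P onset."""
        pq = self.pq_ms if pq_ms is None else pq_ms
        qt = self.qt_ms if qt_ms is None else qt_ms
        return {
            "p_onset": 0.0,
            "p_offset": self.p_duration_ms,
            "qrs_onset": pq,
            "qrs_offset": pq + self.qrs_ms,
            "t_offset": pq + qt,
            "j_point": pq + self.qrs_ms,
        }

    # --- shape pieces, all relative to QRS onset (t = 0 at QRS onset) ---

    def _shapes(self, t_ms: np.ndarray, pq_ms: float, qt_ms: float,
                qrs_ms: float | None = None, with_p: bool = True,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return unit (P, QRS, T) shape arrays sampled at t_ms."""
        qrs = self.qrs_ms if qrs_ms is None else qrs_ms
        p = (self.p_amp_mv * _triangle(t_ms, -pq_ms, -pq_ms + self.p_duration_ms)
             if with_p else np.zeros_like(t_ms))
        q = self.q_rel * _hann_bump(t_ms, 0.0, 0.28 * qrs)
        r = 1.0 * _hann_bump(t_ms, 0.17 * qrs, 0.72 * qrs)
        s = self.s_rel * _hann_bump(t_ms, 0.66 * qrs, qrs)
        qrs_shape = self.r_amp_mv * (q + r + s)
        # T: raised-cosine upstroke then linear downstroke ending exactly at
        # the T offset, so threshold-based offset detection is unbiased.
        t_on = qrs + 0.25 * (qt_ms - qrs)
        t_peak = t_on + 0.55 * (qt_ms - t_on)
        tw = np.zeros_like(t_ms)
        m1 = (t_ms >= t_on) & (t_ms <= t_peak)
        m2 = (t_ms > t_peak) & (t_ms <= qt_ms)
        if t_peak > t_on:
            tw[m1] = 0.5 * (1.0 - np.cos(np.pi * (t_ms[m1] - t_on)
                                         / (t_peak - t_on)))
        if qt_ms > t_peak:
            tw[m2] = (qt_ms - t_ms[m2]) / (qt_ms - t_peak)
        t_shape = self.t_amp_mv * tw
        return p, qrs_shape, t_shape

    def st_bump(self, t_ms: np.ndarray, qrs_ms: float | None = None,
                ) -> np.ndarray:
        """Unit ST-shift shape: flat plateau over the ST window with
        raised-cosine edges, support [J+10, J+140] ms."""
        qrs = self.qrs_ms if qrs_ms is None else qrs_ms
        a, b = qrs + 10.0, qrs + 140.0
        ramp = 25.0
        out = np.zeros_like(t_ms)
        m = (t_ms >= a) & (t_ms <= b)
        x = t_ms[m]
        v = np.ones_like(x)
        up = x < a + ramp
        dn = x > b - ramp
        v[up] = 0.5 * (1 - np.cos(np.pi * (x[up] - a) / ramp))
        v[dn] = 0.5 * (1 - np.cos(np.pi * (b - x[dn]) / ramp))
        out[m] = v
        return out

    def render_beat(self, fs: float, pq_ms: float | None = None,
                    qt_ms: float | None = None,
                    st_offset_mv: np.ndarray | None = None,
                    t_scale: np.ndarray | None = None,
                    ectopic: bool = False) -> tuple[int, np.ndarray]:
        """Render one beat for all 12 leads.

        Returns ``(rel_start, wave)`` where ``wave`` has shape
        (n_samples, 12) and ``rel_start`` is the sample offset of the first
        sample relative to the QRS onset sample.

        st_offset_mv / t_scale are per-lead arrays (len 12) applied to the ST
        plateau and the T amplitude; ectopic beats have no P wave, a wide
        high-amplitude QRS and an inverted T.
        """
        pq = self.pq_ms if pq_ms is None else pq_ms
        qt = self.qt_ms if qt_ms is None else qt_ms
        qrs = 140.0 if ectopic else self.qrs_ms
        if ectopic:
            qt = max(qt, qrs + 160.0)
        lo_ms = -pq
        hi_ms = qt + 5.0
        step = 1000.0 / fs
        rel_start = int(np.ceil(lo_ms / step))
        rel_end = int(np.floor(hi_ms / step))
        t_ms = np.arange(rel_start, rel_end + 1) * step
        p, qrs_shape, t_shape = self._shapes(
            t_ms, pq, qt, qrs_ms=qrs, with_p=not ectopic)
        if ectopic:
            qrs_shape = 1.4 * qrs_shape
            t_shape = -0.6 * t_shape
        st_shape = None
        if st_offset_mv is not None and np.any(st_offset_mv != 0.0):
            st_shape = self.st_bump(t_ms, qrs_ms=qrs)
        wave = np.empty((t_ms.size, len(LEADS)), dtype=np.float64)
        for j, lead in enumerate(LEADS):
            fp, fq, ft = self.lead_factors[lead]
            tj = ft * (t_scale[j] if t_scale is not None else 1.0)
            v = fp * p + fq * qrs_shape + tj * t_shape
            if st_shape is not None:
                v = v + st_offset_mv[j] * st_shape
            wave[:, j] = v
        return rel_start, wave

    def reference_waveform(self, fs: float = 200.0) -> np.ndarray:
        """One reference cycle (RR = rr_ref_ms) per lead, (n, 12) mV,
        starting at the P onset."""
        n = int(round(self.rr_ref_ms / 1000.0 * fs))
        step = 1000.0 / fs
        t_ms = np.arange(n) * step - self.pq_ms  # relative to QRS onset
        p, qrs_shape, t_shape = self._shapes(t_ms, self.pq_ms, self.qt_ms)
        wave = np.empty((n, len(LEADS)))
        for j, lead in enumerate(LEADS):
            fp, fq, ft = self.lead_factors[lead]
            wave[:, j] = fp * p + fq * qrs_shape + ft * t_shape
        return wave
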