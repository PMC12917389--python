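# holterkit

Analysis of multi-day 12-lead ambulatory (Holter) ECG for suspected coronary
vasomotor dysfunction — the setting where patients have angina but no
obstructive coronary disease (ANOCA), and the question is whether
transient, often subtle, ischemic ECG changes recorded at home can flag the
patients whose invasive coronary function test will show coronary artery
spasm (CAS).

The package is a library for researchers working with such recordings. It
covers the full chain:

* **Segmentation** — QRS detection, beat classification (sinus / non-sinus /
  artifact), P/QRS/T delineation, per-10-s medians of heart rate and
  conduction times (PQ, QRS, QT), SDNN per 5 min, and a per-10-s usability
  mask for gaps, artifact bursts and saturation.
* **Heart-rate-matched median beats** — a per-lead median beat for every 10-s
  segment; a patient-specific baseline library in 5-bpm heart-rate bins
  (40–140 bpm); ST deviation measured over the J+40…J+80 ms window and
  min/max T-wave amplitude deviations, each against the baseline beat of the
  matching heart-rate bin after PQ-isoelectric referencing. Measuring against
  the patient's own rate-matched baseline is what makes deviations of
  0.02–0.10 mV — far below the conventional 0.1 mV criterion — interpretable.
* **Ischemia events and burden** — an event is ≥ 30 s (three consecutive
  usable 10-s segments) with the cutoff exceeded in ≥ 2 contiguous leads
  (inferior II–III–aVF, lateral I–aVL–V5–V6, anterior V1–V4, V4–V5 linking);
  burden is total event time normalised to seconds per 24 h of usable
  recording, flagged at ≥ 1 min/day; cutoffs are swept over 0–0.5 mV.
* **Symptoms** — diary and button streams merged (same type within 10 min is
  one symptom), and concurrency scored: an acute symptom (chest pain,
  dyspnea) counts as concurrent when an event overlaps ±30 min of its onset.
* **Circadian and resting assessments** — noon-to-noon day selection, 3-h-bin
  medians of HR/PQ/QRS/QT/QTc/SDNN with group percentile bands, Welch-t or
  Mann-Whitney comparisons gated by Shapiro-Wilk, logistic models adjusted
  for age, sex, beta-blocker and rate-limiting calcium-channel-blocker use,
  and a standardised resting 10 s (symptom-free, 06:30–08:30, heart rate
  closest to 75 bpm) with Bazett QTc.
* **Diagnostics** — 2×2 tables, sensitivity/specificity/PPV/NPV with Wilson
  95% intervals, Fisher exact tests, and rank AUC with a stratified
  1000-resample bootstrap CI.
* **Synthetic cohorts** — a seeded generator producing either full 200 Hz
  waveforms (minutes–hours scale) or per-10-s series (multi-day, cohort
  scale) with circadian rhythms, injected episodes, symptom logs with
  diary/button under-reporting, artifact bursts and daily gaps, plus complete
  ground truth for every injected feature.

## Worked example

```bash
python examples/02_detect_ischemia.py
```

```
1799 beats; usable signal 1800/1800 s
baseline library: 1 heart-rate bin(s), 180 source segments
event 910-1010 s in V4/V5, peak -0.054 mV
normalised burden 4800 s/day (>=60 s/day flag: True)
```

A 30-min synthetic recording carries one injected ST-depression episode of
−0.05 mV in V4/V5 from 900 s to 1020 s. The pipeline detects a single event
bracketing it, in exactly those two contiguous leads, with a peak deviation
equal to the injected amplitude (the deviation is measured against the
patient's own heart-rate-matched baseline beat, so the recovered magnitude is
the injected offset, not an absolute ST level). The burden is the event time
rescaled to a 24-h day.

The other examples simulate a patient with ground truth
(`01_simulate_patient.py`), run cohort-level diagnostics with Wilson
intervals, Fisher tests and bootstrap AUC (`03_cohort_diagnostics.py`), and
compute circadian profiles plus the resting 10-s table
(`04_circadian_profiles.py`).

A thin CLI wraps the same pipeline for shell use:

```bash
holterkit all --n-cas 4 --n-nocas 2 --seed 7 --outdir work
```

## Layout

```
src/holterkit/     library (synthetic, segmentation, median_beat, ischemia,
                   circadian, diagnostics, io, pipeline, cli)
examples/          narrative scripts, one per capability
tests/             pytest suite incl. brute-force oracles
docs/methods.md    models, parameters, numerical choices, limitations
```
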