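# Methods

This note documents the models, parameters and numerical choices behind
holterkit, and what the synthetic validation does and does not establish.

## Problem setting

Patients with angina and non-obstructive coronary arteries (ANOCA) frequently
have coronary artery spasm (CAS), currently diagnosed by invasive
acetylcholine provocation. Multi-day 12-lead Holter monitoring before the
invasive test offers a non-invasive window: transient spasm should leave
ischemic traces (ST depression, T-wave changes) that are too small and too
brief for conventional criteria, and circadian autonomic differences may also
distinguish the groups. The pipeline quantifies both: per-cutoff ischemia
burden with diagnostic accuracy, and circadian conduction-time profiles.

## Deviation measurement model

The central quantity is the deviation of a 10-s segment from the patient's
own heart-rate-matched baseline:

1. Per segment and lead, a **median beat** is formed as the sample-wise
   median of QRS-onset-aligned sinus beats (window −200 ms to +452 ms around
   the QRS onset; at least 3 beats). The median suppresses additive noise and
   single-beat artifacts.
2. A **baseline library** maps 5-bpm heart-rate bins (centered on multiples
   of 5 bpm, spanning 40–140 bpm) to the sample-wise median of all segment
   median beats in the bin, over the whole recording; bins need ≥ 10
   segments. Building the baseline from the full recording maximises bin
   support; if ischemic time were a large fraction of the recording this
   would dilute measured deviations (a known limitation; episodes occupying a
   few minutes per day dilute the baseline negligibly).
3. A segment is compared with its own bin, or the nearest populated bin
   within 10 bpm; otherwise its deviation is absent. **ST deviation** is the
   mean over J+40…J+80 ms (J = QRS offset) minus the same quantity of the
   baseline beat, both referenced to their PQ isoelectric level (mean of
   −40…−10 ms before QRS onset). **T-wave deviations** are the change in the
   min/max amplitude over QRS offset + 80 ms to the T offset. The windows are
   declared constants: a 40-ms mean is robust to noise at 200 Hz, and the
   rate-matching plus isoelectric referencing make the measure a *difference*
   from the patient's own norm, which is what permits cutoffs far below the
   0.1 mV convention.

## Ischemia rule

For a parameter (ST deviation/elevation/depression, min/max T deviation) and
cutoff c: depression qualifies at deviation ≤ −c, elevation at ≥ +c, the
others at |deviation| ≥ c. An **event** is a maximal run of ≥ 3 consecutive
usable 10-s segments in which at least one *contiguous lead pair* exceeds the
cutoff throughout the run (pair-stable rule). Contiguity follows standard
ST-criteria chains: II–III–aVF; I–aVL–V5–V6; V1–V2–V3–V4; V4–V5. The looser
reading — some contiguous pair each segment, not necessarily the same one —
is available as `contiguity_rule="any_pair"`; both are covered by the
brute-force oracle tests. Events are timed on the 10-s grid, so "at least
30 s" means three segments, and an unusable segment breaks a run (no
bridging). **Burden** is total event time × 86400 / usable time, flagged at
≥ 60 s/day; the cutoff grid is 0–0.5 mV in 0.005 mV steps, fine enough to
separate neighbouring cutoffs such as 0.035 and 0.040 mV.

Symptoms from diary and button are merged (same type within 10 min is one
symptom, diary timestamp kept — a declared constant, since the two streams
overlap only partially in practice). An acute symptom (chest pain or dyspnea)
is concurrent if any event overlaps symptom onset ± 30 min, boundaries
inclusive. Patients without acute symptoms contribute a negative flag to the
diagnostic tables and no percentage.

## Circadian and resting assessments

Days are noon-to-noon; a day qualifies with ≥ 50% usable windows (declared).
Profiles are per-3-h-bin medians (8 bins from midnight) of HR, PQ, QRS, QT,
QTc and SDNN; bins with < 10 usable windows are absent. Group comparison uses
Welch's t-test when Shapiro-Wilk accepts normality (p > 0.05) in both groups,
Mann-Whitney U otherwise, two-sided; identical constant groups return p = 1
by convention. Under this gate the realised type-I error at n = 33 vs 9 is
about 0.058 (the Welch approximation at n₂ = 9 plus the selection induced by
the gate), measured by the calibration tests. Logistic models (odds ratio
per unit feature, Wald CI) are fit unadjusted and adjusted for age, sex,
beta-blocker and rate-limiting calcium-channel-blocker use; perfect
separation and non-convergence are flagged, with no estimate reported.

The resting 10 s is the usable, symptom-free (±15 min margin, declared)
window between 06:30 and 08:30 with heart rate closest to 75 bpm (pure
argmin, ties to the earliest window), preferably the day before the recording
ends, falling back one day. QTc is Bazett (QT/√RR[s]); the prolonged-QTc flag
uses the conventional 460/450 ms (F/M) cutoffs, configurable.

## Diagnostics

Wilson score intervals for all proportions (exact 0/1 at the k=0 and k=n
boundaries); Fisher exact tests (two-sided, hypergeometric); AUC by the rank
formulation with half-credit for ties, with a percentile bootstrap CI from
1000 resamples stratified by group to preserve the class imbalance. The AUC
score for the burden analysis is the *continuous* normalised daily burden —
a binary flag cannot produce intermediate AUC values — with the flag-based
AUC also reported. Tests are two-sided at α = 0.05 and no multiple-testing
correction is applied across the cutoff sweep (exploratory analysis; the
output metadata says so).

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study conditions
for all stochastic validation. One patient model drives two tiers:

* **Waveform tier** (200 Hz, 12 leads): beats are rendered from a parametric
  template — triangular P wave, raised-cosine Q/R/S deflections, T wave with
  raised-cosine upstroke and linear downstroke — scaled per lead by typical
  adult factors. Compact wave support makes fiducial ground truth exact and
  keeps the PQ segment isoelectric. RR follows the circadian heart-rate model
  plus Gaussian jitter (default 20 ms); PQ has a nocturnal increment peaking
  at 03:00; QT is tied to RR by a configurable Bazett relation
  (QT = QTc·√RR). ST episodes add a ramped plateau (support J+10…J+140 ms)
  to the affected leads; T episodes scale the T amplitude. Band-limited
  noise (10 µV RMS default), artifact bursts and zero-filled daily gaps are
  added and recorded in the ground truth. Memory is ~0.5 GB per day, so this
  tier is used at minutes-to-hours scale.
* **Series tier**: the same circadian/episode/symptom/artifact models emitted
  directly as per-10-s interval and deviation series (per-segment ST noise
  8 µV SD, declared), for multi-day and cohort-scale studies where waveform
  synthesis adds nothing. The waveform tier validates that segmentation and
  median-beat measurement recover the model; the series tier then stands in
  for that chain at scale.

Study conditions (chosen once): CAS arm — HR mesor 70 bpm, circadian
amplitude 10 bpm (acrophase 15:00), PQ 166 ms (+14 ms nocturnal), QTc
451 ms, ischemia-prone probability 0.88; no-CAS arm — mesor 73 bpm,
amplitude 7.5 bpm, PQ 153 ms (+8 ms), QTc 440 ms, prone probability 0.44
(ischemia-positive patients in the no-CAS arm are the generator's rendering
of the observed low specificity). Prone patients receive ST-depression
episodes at 4/day, amplitudes N(−0.05, 0.02) mV — centred where sub-0.1 mV
cutoffs are discriminative — durations log-normal (median 150 s), on random
contiguous lead groups. Between-patient variation: SD 6 bpm / 18 ms / 20 ms
on mesor, PQ and QTc. Symptoms: background 4.8/day plus, for prone patients,
a probability 0.5 symptom within ±20 min of each episode; reporting is
independent per stream (diary 0.286, button 0.211), values solved so that a
6.65/day true rate reproduces the observed 1.9 diary / 1.4 button / 2.9
merged symptoms per day. Artifacts cover 18% of windows (grid-aligned
bursts, mean 30 s) and one 20-min daily gap at 09:00, yielding ~80% usable
recording. Recording length defaults to 3 days within the 2–7-day wear
protocol.

What passing tests show: the pipeline recovers what the generator injects —
beat times, conduction intervals, ST offsets, burden proportions, symptom
rates — under realistic noise, artifacts and circadian structure. What they
do not show: performance on real morphology variation (axis shifts,
electrode repositioning after showers, bundle-branch block, atrial
fibrillation), non-stationary baselines, or real spasm electrophysiology.
Cohort-level accuracy numbers on synthetic data characterise the code, not
the clinical method.

## Numerical choices and scale

* Delineation runs on lead II (fall-back: largest-amplitude lead) with a
  5–20 Hz energy detector, threshold/slope-based onsets/offsets, and
  reclassifies unresolvable beats as artifact rather than dropping them.
  Recovery tolerances on clean signal: ±10 ms median PQ/QT error, ±1 bpm
  per-window heart rate; beats are non-sinus at QRS > 120 ms or RR deviating
  > 20% from the local median; SDNN needs ≥ 30 NN intervals per 5-min window
  (conventional HRV practice).
* Determinism: every stochastic step flows from explicit seeds
  (`numpy.random.SeedSequence` spawning per patient); the full fixture
  pipeline is bit-reproducible, checked by digesting all output tables.
* Validation problem sizes: burden-proportion recovery uses 1000
  patients/arm (binomial SE ≈ 0.01 at p = 0.88); statistical calibration
  uses 2500 null cohorts; the event-rule oracle covers 500 randomised grids;
  waveform-tier tests use 10–60 min recordings. The cohort generator streams
  patients (`iter_cohort`) to keep memory flat at large n.

## Known limitations

* The delineator is tuned for the template morphology family; real-world use
  would warrant validation against a standard annotated corpus.
* QRS-offset detection is slope-based; during an ST episode the measured QRS
  offset can shift by a few samples, slightly biasing per-beat QT within
  episodes (medians over segments are unaffected).
* The series tier treats per-segment deviation noise as independent across
  segments and leads; real noise is correlated, which would raise the null
  false-positive rate above the (near-zero) synthetic one.
* EDF can be read (via mne) but not written; the native interchange format is
  a plain-text JSON-header + CSV pair.
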