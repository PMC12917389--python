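"""Circadian conduction-time profiles and the standardised resting 10-s
assessment on a simulated cohort.

Run:  python examples/04_circadian_profiles.py
"""

from holterkit import (circadian_profile, compare_bins, generate_cohort,
                       group_profile, merge_symptoms, select_day_window,
                       select_resting_10s)
from holterkit.synthetic import default_cas_spec, default_nocas_spec

cohort = generate_cohort(12, 6, default_cas_spec(), default_nocas_spec(),
                         seed=7)
profiles, labels = [], []
for p in cohort:
    window = select_day_window(p.intervals, "last_full")
    profiles.append(circadian_profile(p.intervals, p.sdnn, window))
    labels.append(p.label == "CAS")

grp = group_profile(profiles, labels)
hr = grp[(grp.measure == "hr_bpm")]
print("median heart rate per 3-h bin (bin 1 = 3-6 AM):")
print(hr.pivot(index="bin", columns="group", values="median").round(1))

tests = compare_bins(profiles, labels)
sig = tests[(tests.p < 0.05)]
print(f"\n{len(sig)} bin/measure comparisons with p < 0.05 "
      f"(test chosen by Shapiro-Wilk gate)")

print("\nresting 10-s selection (symptom-free, 06:30-08:30, HR closest 75):")
for p in cohort[:4]:
    merged = merge_symptoms(p.symptoms, p.spec.start_time)
    r = select_resting_10s(p.intervals, merged)
    if r:
        print(f"  {p.patient_id} ({p.label}): {r.clock_time:%a %H:%M:%S}, "
              f"HR {r.hr_bpm:.1f} bpm, QT {r.qt_ms:.0f} ms, "
              f"QTc {r.qtc_ms:.0f} ms")
# CAS patients show the deeper nocturnal heart-rate dip and longer PQ/QTc;
# the difference is largest in the night and early-morning bins.
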