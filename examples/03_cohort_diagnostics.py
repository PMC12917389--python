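"""Cohort-level diagnostics on a simulated two-group cohort: threshold sweep,
2x2 accuracy with Wilson intervals, Fisher tests and bootstrap AUC.

Run:  python examples/03_cohort_diagnostics.py   (about half a minute)
"""

import numpy as np

from holterkit import analyze_cohort, generate_cohort
from holterkit.synthetic import default_cas_spec, default_nocas_spec

cohort = generate_cohort(33, 9, default_cas_spec(), default_nocas_spec(),
                         seed=2024)
result = analyze_cohort(cohort, seed=2024,
                        sweep_cutoffs=np.round(np.arange(0, 0.21, 0.01), 3))

acc = result.accuracy
burden35 = acc[(acc.criterion == "burden_1min_daily")
               & (acc.cutoff_mv == 0.035)]
print("accuracy of >=1 min/day ST depression >=0.035 mV for CAS:")
for _, r in burden35.iterrows():
    print(f"  {r['metric']:>12}: {r['estimate']:.2f} "
          f"({r['ci_low']:.2f}-{r['ci_high']:.2f})")
print(f"  Fisher p = {burden35['fisher_p'].iloc[0]:.3f}")

auc = result.auc
row = auc[(auc.criterion == "burden_score") & (auc.cutoff_mv == 0.035)].iloc[0]
print(f"AUC of continuous daily burden: {row['auc']:.2f} "
      f"({row['ci_low']:.2f}-{row['ci_high']:.2f}, "
      f"{row['n_bootstrap']} bootstrap resamples)")
# With 33 vs 9 patients the Wilson intervals are wide; the point estimates
# track the injected burden-positive probabilities (0.88 vs 0.44).
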