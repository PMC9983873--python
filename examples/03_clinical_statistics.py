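"""Downstream clinical statistics on a simulated validation cohort.

Generates IHC scores (179 primary tumors, 56 lymph-node metastases, with
LN staining shifted up), a 415-patient survival cohort whose high-marker
group carries twice the event hazard, and positive-lymph-node counts; then
runs the binning, Mann-Whitney, Kaplan-Meier/log-rank, LN-ratio and
correlation analyses.
"""

from collections import Counter

import numpy as np

from metscreen import (
    ClinicalSimConfig,
    ihc_bin_table,
    km_estimate,
    ln_ratio_group,
    logrank_test,
    mann_whitney,
    marker_correlation,
    simulate_clinical,
)
from metscreen.clinical_stats import survival_at

ihc, surv, ln, patients = simulate_clinical(ClinicalSimConfig(seed=1))

print("IHC bins by tissue:")
print(ihc_bin_table(ihc).to_string(index=False,
                                   float_format=lambda v: f"{v:.2f}"))
primary = [r.score for r in ihc if r.tissue == "primary"]
ln_met = [r.score for r in ihc if r.tissue == "ln_met"]
u, p = mann_whitney(ln_met, primary, mode="asymptotic")
print(f"LN-met vs primary scores: Mann-Whitney U={u:.0f}, p={p:.3g}")

low = [r for r in surv if r.group == "low"]
high = [r for r in surv if r.group == "high"]
stat, p = logrank_test(low, high)
km_low, km_high = km_estimate(low), km_estimate(high)
print(f"\n5-year survival: low-marker {survival_at(km_low, 60):.2f}, "
      f"high-marker {survival_at(km_high, 60):.2f}")
print(f"log-rank chi2={stat:.1f}, p={p:.3g}")

groups = Counter(ln_ratio_group(r) for r in ln)
print(f"\nLN-ratio groups (30% cutoff): {dict(groups)}")

# marker-marker correlation on an independent noisy partner profile
rng = np.random.default_rng(2)
x = patients["marker"].to_numpy()
y = 0.2 * x + rng.normal(0, x.std(), len(x))
for method in ("spearman", "pearson"):
    r, p = marker_correlation(x, y, method)
    print(f"{method} correlation with partner profile: r={r:.3f}, p={p:.3g}")
print(
    "\nHigher IHC bins in LN metastases, the survival split and the high-"
    "ratio group mirror the validation analyses a marker-level screen feeds."
)
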