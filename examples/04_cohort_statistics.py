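"""Patient-level statistics on a synthetic cohort drawn from the published
group distributions: rater agreement (ICC), normality-gated group tests and
single-marker ROC analysis.
"""
import numpy as np

from vetcdiff import CohortConfig, average_raters, roc_analysis, sample_patients
from vetcdiff.stats import select_and_compare
from vetcdiff.voi import cohort_icc_table

records = sample_patients(CohortConfig(seed=42))
labels = np.array([1 if r.vetc_status == "positive" else 0 for r in records])
means = [average_raters(r) for r in records]

print("inter-rater ICC (first rows):")
print(cohort_icc_table(records).round(3).head(4), "\n")

for marker in ("ADC", "DKI_K", "CTRW_alpha"):
    vals = np.array([m[marker] for m in means])
    comp = select_and_compare(vals[labels == 0], vals[labels == 1],
                              marker=marker)
    line = (f"{marker:10s} {comp.test_used:12s} p={comp.p_value:.4f}  "
            f"neg {comp.mean_neg:.2f}±{comp.sd_neg:.2f}  "
            f"pos {comp.mean_pos:.2f}±{comp.sd_pos:.2f}")
    if comp.p_value < 0.05:
        r = roc_analysis(vals, labels)
        line += (f"  AUC={r.auc:.3f} cutoff={r.youden_cutoff:.3f} "
                 f"youden={r.youden_index:.3f}")
    print(line)
print("\nAs in the study, the kurtosis and CTRW temporal exponent separate"
      "\nthe groups (p < 0.05) while ADC does not; their AUCs land near the"
      "\npublished 0.678/0.672.")
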