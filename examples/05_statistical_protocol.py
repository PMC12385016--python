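"""The statistical validation protocol on worked numbers.

Metric identities from confusion counts, paired tests on five fold
scores, an exact McNemar comparison, and Holm-Bonferroni adjustment of a
family of p-values.
"""

from gradiomics.stats import (
    holm_bonferroni,
    metrics_from_counts,
    paired_t,
    wilcoxon_signed_rank,
)

# a test set of 457 roots: 238 lesioned, 219 healthy
m = metrics_from_counts(tp=227, fn=11, tn=217, fp=2)
print(f"sensitivity {m.sensitivity:.1%}   specificity {m.specificity:.1%}   "
      f"accuracy {m.accuracy:.2%}")
print(f"missed lesions {m.missed_lesion_rate:.1%}   "
      f"mislabeled healthy {m.mislabeled_healthy_rate:.1%}\n")

# five paired fold accuracies: does the variant beat the baseline?
baseline = [0.952, 0.958, 0.949, 0.961, 0.955]
variant = [0.960, 0.964, 0.957, 0.969, 0.961]
t = paired_t(variant, baseline)
w = wilcoxon_signed_rank(variant, baseline)
print(f"paired t: t={t.statistic:.2f}, p={t.p_value:.4f}")
print(f"Wilcoxon (exact, n=5 same-sign): W={w.statistic:.0f}, p={w.p_value:.4f}\n")

# a family of three comparisons at alpha = 0.05
p_family = [0.01, 0.03, 0.04]
reject, adjusted = holm_bonferroni(p_family, alpha=0.05)
for p, r, adj in zip(p_family, reject, adjusted):
    print(f"raw p={p:.3f} -> adjusted {adj:.3f} -> {'reject' if r else 'keep'} H0")
print("\nOnly the smallest p-value survives the step-down family-wise correction.")
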