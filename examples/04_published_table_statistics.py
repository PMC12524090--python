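"""Recompute the worked statistical examples from the shipped reference tables.

The package ships the published accuracy tables of a dual-branch
semi-supervised brain-tumor MRI study as CSV inputs.  This script feeds them
through the statistics suite and prints each derived quantity next to its
published value: McNemar's χ² on the paired 2×2 outcomes, binomial
confidence intervals for selected splits, Cohen's d effect sizes, and the
paired mean accuracy differences that the one-tailed t-test is built on.
"""

from pseudofuse import datasets
from pseudofuse.stats import binomial_ci, cohens_d, describe, mcnemar_test, paired_t_test

table = datasets.load_contingency_table()
res = mcnemar_test(table)
print(f"McNemar chi2 = {res.chi2:.2f} (published 4.36), p = {res.p:.3f} (published 0.037)")
print(f"agreement rate = {table.agreement_rate:.1f}% (published 96.6%)")
print(f"misclassification: model {table.model_misclassification_rate:.2f}% "
      f"vs baseline {table.baseline_misclassification_rate:.2f}%\n")

for _, row in datasets.load_accuracy_ci_inputs().iterrows():
    ci = binomial_ci(row["accuracy_pct"] / 100, int(row["n_test"]))
    print(f"split {row['split']}: accuracy {row['accuracy_pct']:.2f}% -> "
          f"95% CI [{ci.lower:.2f}, {ci.upper:.2f}], SE {ci.standard_error:.5f}")

print()
for _, row in datasets.load_effect_size_inputs().iterrows():
    d = cohens_d(row["ssl_mean"], row["ssl_sd"], 9,
                 row["supervised_mean"], row["supervised_sd"], 9)
    print(f"split {row['split']}: Cohen's d = {d.d:.2f} (pooled SD {d.pooled_sd:.2f})")

print()
for model in ("custom_cnn", "resnet50"):
    t = paired_t_test(datasets.paired_table(model))
    mean_sup, sd_sup = describe(datasets.load_paired_accuracy()[f"supervised_{model}"])
    print(f"{model}: supervised mean {mean_sup:.2f}%, paired mean gain "
          f"{t.mean_diff:+.2f} points, t({t.df}) = {t.t:.2f}, one-tailed p = {t.p_one_tailed:.4f}")
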