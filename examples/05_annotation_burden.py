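"""Annotation-burden reduction from performance-vs-budget curves.

Performance grows roughly logarithmically with the number of manually
labeled exams, so observed budgets are interpolated linearly in log(n).
The worked numbers reproduce the published matched budgets: supervised
training on 2440 per-fold exams matched by semisupervised training with
169 (exam-level) / 431 (lesion-level) manual labels.
"""

from rgpl import (
    PerformanceCurve,
    annotation_reduction_factor,
    interpolate_performance,
    matched_budget,
    per_fold_training_size,
)

# Published worked examples: matched budgets -> reduction factors.
for n_semi, label in ((169, "exam-level AUC"), (431, "lesion-level pAUC")):
    r = annotation_reduction_factor(2440, n_semi)
    print(f"{label}: 2440 supervised vs {n_semi} semisupervised labels "
          f"-> factor {r.factor:.1f} (rounded {r.rounded})")

print(f"budget 3050 at 5-fold cross-validation trains each model on "
      f"{per_fold_training_size(3050, 5)} exams")

# Interpolating a semisupervised curve to find where it matches a target.
ssl = PerformanceCurve(budgets=(100, 300, 1000, 3050),
                       metric_values=(0.84, 0.87, 0.89, 0.90),
                       metric_name="auc")
target = 0.86
n = matched_budget(ssl, target)
print(f"semisupervised curve reaches AUC {target} at ~{n:.0f} manual labels; "
      f"check: interpolated AUC there = {interpolate_performance(ssl, n):.3f}")
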