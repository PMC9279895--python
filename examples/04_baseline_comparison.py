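"""Compare kernel fusion with conventional stacked-feature learners.

Every method is evaluated with the identical LOOCV protocol: linear SVM,
random forest, gradient boosting and an MLP on the concatenated feature
vector, plus single-modality linear SVMs.  On cohorts with strong clinical
and weak imaging signal, stacking dilutes the clinical block and the weak
modalities alone hover near chance.
"""

import pandas as pd

from mkfusion import (
    CohortSpec, baseline_harness, default_kernel_specs, generate_cohort,
    nested_weight_search, simplex_grid,
)

dataset = generate_cohort(CohortSpec(), seed=1)

rows = []
for method, modality in [("svm", "clinical"), ("svm", "eeg"), ("svm", "pet"),
                         ("svm_stacked", "all_stacked"),
                         ("random_forest", "all_stacked"),
                         ("gradient_boosting", "all_stacked"),
                         ("mlp", "all_stacked")]:
    res = baseline_harness(dataset, method=method, modality=modality, seed=1)
    rows.append({"method": method, "modality": modality, **res.metrics})

fusion = nested_weight_search(dataset, default_kernel_specs(dataset),
                              grid=simplex_grid(3, 0.2), seed=1)
rows.append({"method": "mk_svm (fusion)", "modality": "combined",
             **fusion.metrics})

print(pd.DataFrame(rows).to_string(index=False))
print("\nEach row is LOOCV over the same 52 subjects; AUC near 0.5 for the")
print("imaging-only models and a fused AUC above every baseline mirror the")
print("motivating analysis.")
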