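"""Simulate a multimodal case-control cohort and screen its features.

Generates the default 28-case / 24-control cohort — clinical questionnaire
totals drawn from published-style group summaries, EEG band power (266
features) and PET regional uptake (90 ROIs) as correlated Gaussians with
weak group shifts — then runs a per-feature Welch t screen.
"""

from mkfusion import CohortSpec, feature_screen, generate_cohort

dataset = generate_cohort(CohortSpec(), seed=1)
print(f"subjects: {dataset.n} "
      f"({int((dataset.y > 0).sum())} cases, {int((dataset.y < 0).sum())} controls)")
for m in dataset.modalities:
    print(f"  {m}: {dataset.blocks[m].shape[1]} features")

screen = feature_screen(dataset)
sig = screen.groupby("modality")["significant_bonferroni"].sum()
print("\nBonferroni-significant features per modality (alpha = 0.05):")
print(sig.to_string())
print("\nThe clinical block carries nearly all the univariate signal; the")
print("imaging modalities have visible mean shifts but few significant")
print("features — the regime where kernel fusion has something to add.")
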