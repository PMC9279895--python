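# Methods

`mkfusion` implements a multiple-kernel support-vector-machine (MK-SVM)
analysis for small multimodal case-control cohorts, together with a
synthetic-cohort generator that reproduces the statistical structure such
analyses assume.  This note records the model, the defaults and the design
choices a maintainer would want to know.

## Model

Each subject *i* carries a feature vector $x_i^{(m)}$ per modality *m*
(clinical questionnaire totals, EEG spectral power, PET regional glucose
uptake) and a label $y_i \in \{+1, -1\}$ (case / control).  Per modality a
kernel $k^{(m)}(x_i, x_j)$ is computed and the fused kernel is the convex
combination

$$k(x_i, x_j) = \sum_m \beta_m\, k^{(m)}\!\left(x_i^{(m)}, x_j^{(m)}\right),
\qquad \beta_m \ge 0,\ \ \sum_m \beta_m = 1 .$$

The simplex constraint makes $\beta$ interpretable as modality
contributions.  The classifier is the standard soft-margin SVM in the dual:

$$\max_\alpha\ \sum_i \alpha_i - \tfrac12 \sum_{i,j}
\alpha_i \alpha_j y_i y_j k(x_i, x_j)
\quad\text{s.t.}\quad \sum_i \alpha_i y_i = 0,\ \ 0 \le \alpha_i \le C,$$

with decision function $f(z) = \sum_i y_i \alpha_i^* k(x_i, z) + b$.  Only
the kernel changes relative to a single-modality SVM; the optimisation is
untouched.

## Kernels

* Default family: **linear on z-scored features** for every modality.  With
  p ≫ n blocks (266 EEG, 90 PET features against ~50 subjects) a linear
  kernel is the conventional choice; an RBF kernel (fixed γ or the median
  heuristic γ = 1/(2·median²) of pairwise training distances) is available.
* **Unit-diagonal normalisation** $K'_{ij} = K_{ij}/\sqrt{K_{ii}K_{jj}}$ is
  applied before combination.  Without it, β confounds modality scale with
  modality information; with it, every modality contributes a correlation-
  like kernel with diagonal 1.
* **Leakage control**: standardisation statistics and the median-heuristic
  bandwidth are computed from the training rows of the current fold only,
  at every level of the nested CV.  Zero-variance features (on the training
  rows) are dropped with a warning.

## Solver

The dual is solved by sequential minimal optimisation with
maximal-violating-pair working-set selection (the LIBSVM strategy): the
pair with the largest Karush–Kuhn–Tucker violation receives an exact
two-variable update until the violation falls below 1e-8 (well inside the
1e-6 contract asserted by the tests).  Updated coordinates within 1e-12·C
of a box bound are snapped to the bound — round-off can otherwise strand a
coordinate infinitesimally inside the box, where the same pair is
reselected with zero progress.  The bias *b* is the mean of
$y_i - \sum_j \alpha_j y_j K_{ij}$ over margin support vectors
(ε < α < C−ε with ε = 1e-8·C); when no margin SV exists it falls back to
the midpoint of the feasible interval implied by the bound SVs.  Any solver
meeting the same KKT tolerance would be interchangeable; tests verify the
dual objective against an independent SLSQP quadratic-programming solve and
scikit-learn's SVC on precomputed kernels.

Default C = 1.0.  The regularisation parameter of the original analysis is
not documented anywhere we could rely on, so C is exposed and can be
searched over (e.g. {0.1, 1, 10}) in the inner CV alongside β.

## Evaluation protocol

* **Outer loop**: leave-one-out CV (LOOCV) — appropriate at n ≈ 50 and the
  protocol replicated here.  Each held-out subject receives exactly one raw
  decision score; pooled scores give the reported ROC/AUC (with one point
  per fold, pooling is the only coherent aggregate) and, via their signs,
  the confusion matrix.  A score of exactly zero maps to the case class.
* **Inner loop**: stratified 5-fold CV on each outer training set, seeded
  from the master seed plus the outer-fold index.  Every candidate (β, C)
  on an exhaustive simplex grid is scored by the AUC of the pooled inner
  validation scores.
* **Grid**: all weight vectors with entries that are multiples of a step
  1/k, C(k+M−1, M−1) points in lexicographic order.  The library default is
  step 0.05 (231 points for three modalities), consistent with the
  two-decimal weights the protocol reports.  The heavy simulation suites
  and the acceptance script use steps 0.2–0.25 to keep run times in minutes;
  this changes grid resolution only, not the cohort conditions.
* **Tie-break**: with ~n pooled validation scores the inner AUC takes few
  distinct values and frequently ties at its maximum across many candidates
  (on well-separated cohorts, at exactly 1.0).  Selecting the
  lexicographically first tied grid point turns the selection into an
  artifact of modality ordering — in weight-recovery simulations it handed
  the largest weight to a pure-noise modality.  The default is therefore
  the **centroid of all tied top-AUC weight vectors**: deterministic,
  symmetric in the modalities, and a better point estimate of the optimal
  region (ties on C resolve to the smallest C).  `tie_break="first"`
  restores the lexicographic rule.
* **Fixed-weight LOOCV** reruns plain LOOCV with β frozen (typically at the
  fold-averaged weights), which is the protocol behind the reported
  confusion matrices.
* **Contributions** are reported as mean ± sample (n−1) SD of the selected
  weights over outer folds; each fold's β lies on the simplex, so the means
  sum to 1.
* **Baselines** run the identical LOOCV with scikit-learn / xgboost
  learners (linear SVM, random forest with 200 trees, gradient boosting
  with 100 depth-3 trees, an MLP with one width-32 hidden layer and early
  stopping) on a single modality or on all features stacked into one
  vector.  Features are z-scored per training fold.  Scores are decision
  values where available, otherwise centred class probabilities.

## Metrics

Accuracy, sensitivity (recall over cases) and specificity (over controls)
are percentages rounded to one decimal; either rate is an explicit error
when its denominator is empty.  The AUC is the trapezoidal ROC area, which
equals the Mann–Whitney concordance probability with ties counted 1/2; the
test suite verifies this identity by pair enumeration.  The per-feature
screen is Welch's two-sample t-test with a per-modality Bonferroni
threshold 0.05/p_m (266 EEG features give 1.88e-4).

## Synthetic cohorts

The generator emulates a 28-case / 24-control cohort:

* **Clinical block** — one Gaussian per group per feature, parameterised by
  the published-style group means/SDs of a 12-score battery (age, internet
  addiction severity, depression, anxiety, inhibition/activation,
  aggression, impulsiveness, stress, emotional control, resilience,
  quality of life).  Most scores separate the groups strongly (d ≈ 1–2.5).
  Age (no group difference) and the addiction-severity score (it
  quasi-defines the label) are generated but excluded from the default
  classifier block.  Negative draws are clipped at 0 because questionnaire
  scales are bounded below; clipping is recorded in provenance.  The
  clipping truncation biases means of near-zero scores by up to ~9%, so the
  large-n calibration test exercises the Gaussian engine with clipping
  disabled.
* **EEG / PET blocks** — unit-variance Gaussians with exchangeable
  within-modality correlation ρ = 0.3 (a single shared factor per subject)
  and a group mean shift of d·σ per feature: d = 0.1 for most features and
  d = 0.4 for a random 5%.
* **Shift direction** — by default all features of a modality shift
  **coherently** (same sign), the pattern of global band-power or
  metabolism differences.  A coherent shift lies along the shared-factor
  noise axis, so the multivariate signal stays weak (single-modality LOOCV
  AUC ≈ 0.5–0.65) even though individual features show visible mean
  differences — exactly the regime the fusion analysis addresses.  With
  `effect_direction="random"` each feature's sign is drawn independently;
  the shift is then nearly orthogonal to the shared factor and the
  aggregate becomes easy to classify (AUC ≈ 0.75 at the same per-feature
  d), which is useful for weight-recovery experiments where a modality
  must carry unambiguous signal.
* Determinism: identical (spec, seed) gives bit-identical cohorts; the
  three blocks use independent substreams of one seed sequence.

What the generator does **not** model: subscale structure of the
questionnaires (totals only), non-Gaussian marginals, spatial channel/ROI
correlation structure beyond exchangeability, cross-modality correlation,
site or session effects, and any raw-signal provenance (waveforms, images).
Passing simulations therefore show that the pipeline recovers the structure
it assumes — not that real EEG/PET cohorts satisfy that structure.

## Kernel interpretation

Kernel PCA eigendecomposes the double-centered kernel
$K_c = K - \mathbf{1}K/n - K\mathbf{1}/n + \mathbf{1}K\mathbf{1}/n^2$;
subject scores are $v_c\sqrt{\lambda_c}$ with a deterministic sign
convention (largest-magnitude loading positive).  Centering before the
eigendecomposition is the standard choice.  The two-PC separation line is
an unpenalised logistic fit; when the classes are perfectly separated (the
MLE diverges) the maximum-margin direction is reported instead, with a
flag.  Heatmaps reorder subjects cases-first (then by id) so a
group-separating kernel shows four blocks; SVG output fixes the matplotlib
hash salt and omits date metadata so identical inputs yield identical
bytes.

## Problem sizes used by the test and acceptance suites

Simulation-based checks run 10 seeded cohorts of n = 52 each: weight
recovery uses a step-0.25 grid with signal confined to EEG (all features at
d = 1.5, random signs, clinical nulled, PET at d = 0); the modality-ordering
comparison uses the default cohort calibration with a step-0.2 grid.
Deterministic solver and kernel checks use random PSD kernels with 8–16
subjects.  These sizes are chosen so the full suite completes in minutes on
one CPU while leaving the cohort conditions (group sizes, effect sizes,
correlation) at their defaults.

## Known limitations

* The SMO solver is written for the n ≤ a-few-hundred regime of LOOCV
  studies; it keeps the full kernel and Q matrices in memory.
* Only one kernel per modality; no kernel-alignment or learned-kernel
  extensions; binary labels only; no probability calibration.
* The inner-AUC surface over the simplex grid is piecewise constant at
  small n, so selected weights have high fold-to-fold variance — reported
  deliberately as mean ± SD rather than a single vector.
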