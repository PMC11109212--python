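# Methods

This note documents the models and procedures implemented in `mklfusion`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-cohort experiments do and do not
demonstrate.

## Kernel pipeline

Each modality is a subjects-by-features matrix. Its kernel is the plain
dot-product Gram matrix; nonlinear kernels are deliberately out of scope.
Kernels are **trace-normalized** — scaled so the train-train block has trace
`n_train` — before combination, so that a modality with 84 features and one
with 4851 contribute on comparable scales. Trace normalization is the
convention of the EasyMKL literature; unit-diagonal (cosine) normalization
is available via `kernel_normalization="unit_diagonal"`. Two related choices
are exposed but off by default, because nothing in the protocol being
emulated determines them: per-feature z-scoring by train statistics before
the dot product (`standardize_kernel_features`), and kernel centering (not
implemented — documented as off). All normalization statistics come from
train rows only and are then applied to test rows, so no information leaks
from test subjects into training; `build_kernel_set` enforces disjoint
train/test index sets.

## KOMD and EasyMKL

The inner problem is the margin-distribution QP

    min over γ ∈ Γ   (1 − λ) γᵀ Ŷ K Ŷ γ + λ ‖γ‖²

over the bi-simplex Γ (γ ≥ 0, per-class sums equal to 1), Ŷ = diag(y).
The quadratic term is the squared distance between the two γ-weighted class
hull points in kernel feature space; λ ∈ [0, 1] interpolates between pure
hull-separation (λ = 0, a hard-margin-like problem) and the per-class
uniform solution (λ = 1, class centroids).

EasyMKL: (1) solve KOMD on the unweighted sum of normalized kernels;
(2) set η_r ∝ γᵀ Ŷ K_r Ŷ γ, normalized to sum 1; (3) re-solve KOMD on the
composite kernel Σ η_r K_r. The emulated protocol says only that the
composite kernel is "provided to a SVM"; whether that meant the KOMD
classifier itself or a separately trained hinge-loss SVM is ambiguous. The
default here is to re-solve KOMD (step 3); `final_classifier="svm"` trains
`SVC(kernel="precomputed")` on the composite kernel instead. The decision
bias is set to the midpoint of the γ-weighted class-hull scores; it shifts
all scores uniformly and has no effect on AUC.

**Solver.** The QP is solved by monotone FISTA (accelerated projected
gradient with restart), projecting onto each class simplex, step 1/L with L
the largest Hessian eigenvalue, run to a Frank-Wolfe gap of 1e-10 relative
to the objective — comfortably past the 1e-8 contract. The path is fully
deterministic; the acceptance suite checks it against a 0.01-step
brute-force grid over the bi-simplex and against 10⁴ random feasible
points.

**λ default.** λ = 0.1: a small ridge for numerical stability that leaves
the margin term dominant. The protocol being emulated never states λ. Note
(see "Findings" below) that several qualitative behaviors of the pipeline
depend on λ more strongly than on anything else.

**Primal weights.** For linear kernels,
w_r = η_r · c_r · Σ_i γ_i y_i x_i⁽ʳ⁾ with c_r the stored trace-normalization
constant. The concatenated primal scores reproduce the kernel-space decision
scores to 1e-8 (tested property, 20 seeded fits).

## Baselines

* Unimodal: `SVC(kernel="linear")` at C = 1 on per-feature z-scored data
  (train statistics; constant features map to zero). C is not tuned — the
  emulated design is flat, and the package keeps it that way.
* Early fusion: the same SVM on the horizontal concatenation of z-scored
  modalities. Z-scoring is the package's answer to the dimensionality
  imbalance (84 vs 4851 features); raw concatenation is available via
  `scale_early_fusion=False`.
* Stacking (late fusion): per-modality SVMs produce out-of-fold decision
  scores on the train set (5 stratified inner folds), a ridge-penalized
  logistic meta-learner combines them, and base models are refit on the full
  train set for test scoring. The inner-fold count and meta-learner are this
  package's rendering of the named method; the source protocol gives no
  details.

## Evaluation protocol

100 Monte-Carlo splits, stratified 75%/25%, per-class train counts by
round-half-up (11 positives → 8 in train). Split seeds derive from the
master seed through a named substream, as do permutation and stacking
seeds, so families share identical splits (paired comparison) and any stage
can be reproduced in isolation. Metrics: median across splits of the
Mann-Whitney ROC AUC (ties get half credit) and of the step-wise
precision-recall AUC (trapezoidal variant behind a switch). Significance:
each permutation replicate shuffles every split's test labels, the median
AUC across splits is the null statistic, and p = (1 + #{null ≥ observed}) /
(B + 1) — the add-one estimator, never exactly zero. Whether the original
analysis permuted within splits exactly this way is not stated; the choice
matches the reported statistic (a median across splits) and is calibrated:
under a global null the rejection rate at 5% measures 0.045 (n = 200
repetitions, B = 99).

## Stability analysis

Per model family and modality, the per-split primal weight vectors are
unit-normalized and stacked (zero vectors — a modality with η_r = 0 — are
dropped with a warning). PCA is fit **jointly** on all panels being
compared so that, e.g., the unimodal-SVM panel and the MKL panel of one
modality share axes; the source figures do not state whether the fits were
joint or separate. Zero-variance panels report explained-variance fractions
of 0 rather than erroring. No sign alignment is applied across splits: the
labels are fixed, so w and −w are genuinely different classifiers.
The scalar summary, **dispersion** = mean pairwise cosine similarity across
splits, is this package's own addition (1 = identical directions, ≈ 0 =
unrelated); top-feature reports rank by mean absolute weight with
lexicographic tie-breaking.

## Synthetic cohorts

The generator draws, per subject, `n_shared_factors` latent factors common
to all modalities and `n_private_factors_per_modality` modality-specific
factors, every factor N(0, 1) with a class-mean separation of `effect_size`
(in latent SD units). Modality r is `snr_r · (latents @ loadings) + noise`,
loadings drawn once per seed and scaled by 1/√(k_total), noise N(0,
noise_sd²). A modality with snr 0 carries no label information by
construction. The random stream is consumed in an order independent of
`effect_size`, so cohorts with the same seed and different effect sizes
share noise and loadings exactly — the basis of the monotonicity tests.
Subject order is shuffled after generation.

Defaults and presets:

* `paper_like_preset(scenario)` — class counts 43/31 (`chr_vs_control`) or
  11/32 (`converter_vs_nonconverter`); four modalities named
  structural / fmri_fc / dti_fa / dti_md with widths 84 / 4851 / 4304 /
  2152 and snr 1/1/1/0. The dti_md width is the package's choice (half the
  diffusion width); only its snr = 0 status matters. 3 shared + 2 private
  factors, noise_sd 1, fixed seed 1234.
* `effect_size = 0.4` (default): calibrated once so that the best
  single-modality median AUC on the converter preset falls in the 0.6-0.75
  band that studies of this cohort size report. Larger values (≥ 0.8) push
  every family to AUC ≈ 1, which is not a regime any 43-subject
  neuroimaging analysis inhabits.
* `reduced_preset` — widths 84/500/400/100 for fast simulation studies;
  all simulation-based tests and the acceptance script use it. Results at
  full widths are qualitatively identical; reduced widths keep the complete
  test suite under a minute.
* `synergy_preset` — 2 shared + 3 private factors, effect size 0.5:
  complementarity-dominant cohorts in which each modality carries unique
  label information. This is the scenario for fusion-advantage studies: in
  redundancy-dominant cohorts near the signal floor, "best of three
  unimodal AUCs" wins by selection noise alone, which says nothing about
  fusion.

**What the generator does not emulate.** Gaussian class-conditional
distributions with a single class-mean shift: no site or scanner effects,
no subject clusters, no heavy tails, no feature-block correlation beyond
the latent factors, no missing data. Two consequences matter for
interpreting results (next section).

## Findings from the synthetic experiments

Two qualitative claims from the motivating analysis do **not** reproduce
under this package's defaults, for reasons the experiments localize
precisely; both are left as observable (failing) checks rather than being
papered over.

1. *Kernel weights do not suppress a pure-noise modality.* The EasyMKL
   weight d_r = γᵀŶK_rŶγ contains the self-similarity term
   Σ γ_i² K_r(i,i), which for a trace-normalized noise kernel (K ≈ I) is
   ≈ ‖γ‖² > 0 regardless of labels. The acceptance script recomputes the
   mean η of the snr = 0 modality (≈ 0.2-0.3 at the default λ) — roughly a
   uniform share, not ≈ 0; the self-similarity term persists at every λ
   (γ uniform at λ = 1 still gives ‖γ‖² > 0). This is consistent with the practice
   of excluding a chance-level modality from fusion *manually* after
   unimodal screening, which is exactly what the `exclude_modalities`
   mechanism supports.
2. *MKL does not stabilize weak-modality weights at λ = 0.1.* Dispersion of
   the low-snr modality's weight panel is statistically indistinguishable
   between MKL and its unimodal SVM (both sit at the ~0.75 cosine baseline
   set by train-set overlap). The effect appears as λ → 1, where γ
   approaches the uniform class-mean weighting — the acceptance script
   recomputes the comparison at λ = 0.9 alongside the default and reports
   both win rates. Two ingredients are missing at defaults: the
   Gaussian generator produces no multi-stable unimodal SVM solutions (real
   cohorts' cluster structure does), and the sparse γ of small-λ KOMD
   tracks hull-defining subjects, adding variance of its own.

The fusion advantage itself (median AUC of MKL ≥ best unimodal within 0.02)
does reproduce on complementarity-dominant cohorts: 9/10 cohorts at the
`synergy_preset` conditions, 100 shared splits each.

## Numerical choices and degenerate inputs

* QP tolerance: Frank-Wolfe gap ≤ 1e-10 relative; max 2·10⁵ iterations.
* Non-PSD kernels beyond −1e-8 (relative) raise, naming the minimum
  eigenvalue; all-zero kernels raise a degenerate-kernel error naming the
  modality.
* Constant features z-score to 0, never NaN.
* η ties for byte-identical kernels are exact by construction (equal d_r);
  no randomness anywhere in the solver path.
* Problem sizes in tests and the acceptance script (reduced widths, 15-100
  splits, B = 99-999, 10-200 repetitions) are the package's chosen balance
  of statistical resolution against a complete-suite runtime of about a
  minute.

## Known limitations

* The synthetic world validates the machinery, not the clinical claim: a
  pipeline that passes every check here can still behave differently on
  real, heterogeneous cohort data (see the two findings above for concrete
  examples of what Gaussian cohorts cannot exhibit).
* Binary classification only; no nested hyperparameter selection; no
  confidence intervals beyond the permutation test; feature tables only (no
  image-format handling).
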