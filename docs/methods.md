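# Methods

## Geometry

Trial covariances `C = X Xᵀ/(t−1)` are treated as points on the SPD manifold
with the affine-invariant metric. No mean subtraction is applied by default
(band-pass-filtered EEG is approximately zero-mean); an optional `center`
flag subtracts channel means. Whenever `λ_min/λ_max < 1e−10` a relative
ridge `1e−8 · tr(C)/n · I` restores strict positive definiteness without
materially changing the geometry (rank-deficient epochs, flat channels).

All matrix functions (log, exp, square root, inverse square root) go through
symmetric eigendecompositions with eigenvalues clipped at `1e−12` before
logs or inverse powers, which preserves symmetry exactly. The Fréchet mean
uses the standard fixed point
`M ← M^{1/2} exp(mean_k log(M^{−1/2} C_k M^{−1/2})) M^{1/2}`, initialized at
the arithmetic mean, tolerance `1e−8` on the tangent-mean norm, at most 50
iterations (non-convergence returns the last iterate with a warning). The
geodesic distance is computed from the generalized eigenvalues of the pair
`(C₁, C₂)` — algebraically identical to `‖log(C₁^{−1/2}C₂C₁^{−1/2})‖_F` but
one decomposition cheaper.

### What alignment does and does not remove

For a domain observed through a congruence `C ↦ AᵀCA`, aligning by the
domain's own Fréchet mean transforms the aligned matrices by a *fixed
orthogonal* conjugation `B = (AᵀMA)^{−1/2}AᵀM^{1/2}`. Pairwise distances,
identity-centering and the Gram matrix of the tangent features are therefore
exactly invariant for any invertible mixing — but the feature vectors
themselves agree only up to that rotation. For SPD mixing the rotation is
second-order in the commutator of the mixing with the domain mean and is
numerically small (a few percent for condition numbers ≤ 2); for general or
sign-indefinite mixing it can be arbitrary. This is why the synthetic
generator draws SPD mixing matrices, why the invariance tests assert exact
Gram-matrix identity (general mixing) plus close feature agreement (SPD
mixing), and why downstream accuracy under an SPD re-observation of a domain
is tested as stable to a trial or two rather than bitwise equal.

## Tangent features

The log map at the identity is the matrix log of the aligned covariance
(the full expression `M_R^{−1/2} log_{M_R}(C) M_R^{−1/2}` collapses to this
once the domain is aligned — one eigendecomposition instead of three). The
half-vectorization walks the upper triangle column by column —
(1,1); (1,2),(2,2); (1,3),(2,3),(3,3); … — with weight 1 on the diagonal and
√2 off it, so vector 2-norms equal matrix Frobenius norms and the map is
exactly invertible. Feature dimension is `d = n(n+1)/2`.

In the semisupervised path the labelled and unlabelled target partitions are
aligned *separately*, each with its own mean; the source subjects are
aligned per subject and then concatenated into one labelled source domain.

## The adaptation objectives

With features as rows and `N` the one-hot matrix of a domain divided
column-wise by its own class counts (an empty class drops its term for the
iteration, with a warning), the class-mean term of a domain is `NᵀXP`
(2 × q). The three variants differ in which domains enter the MMD and in
the block layout:

* MEKT (blocks [S; T], target fully unlabelled):
  `‖N_SᵀF_SᵀP_S − N_TᵀF_TᵀP_T‖²`, source within-class scatter,
  graph Laplacian of the target, coupling `‖P_S−P_T‖² + ‖P_T‖²`;
  constraint matrix `diag(S_b, F_T H F_Tᵀ)`.
* sMEKT (blocks [S; TL], both labelled): source-vs-labelled-target MMD and
  source scatter only — no graph term (10 trials cannot express the target
  geometry) and no coupling; constraint `diag(S_b, 0)`. Single solve, no
  iterations; fully deterministic.
* ssMEKT (blocks [S; T; TL]): the two labelled domains act jointly against
  the unlabelled target, `‖N_SᵀF_SᵀP_S + N_TLᵀF_TLᵀP_TL −
  N_TUᵀF_TUᵀP_T‖²`; graph and variance terms use the concatenated target
  `F_T = F_TL ∪ F_TU` under the whole-target projection `P_T`; coupling
  `‖P_S−P_T‖² + ‖P_TL−P_T‖² + ‖P_T‖²`.

Weights default to α=1, β=0.01, γ=0.1, θ=20, μ=1e−3, heat-kernel scale σ=1,
K=10 graph neighbours, subspace dimension q=10, five pseudo-label
iterations for MEKT/ssMEKT. The KNN graph uses Euclidean neighbours
excluding self, union symmetrization `max(W, Wᵀ)` (the directed rule as
printed is asymmetric and would not give a symmetric PSD normalized
Laplacian), and K clamped to n−1 with a warning on small domains.

### The eigen-solver

Stationarity of the Lagrangian gives `S_L P = λ S_R P` with a fixed
multiplier μ and a singular constraint matrix `S_R`. The solved pencil is
`(S_L + μI) p = λ S_R p`, keeping the q eigenvectors of smallest *finite* λ
(computed as the largest eigenvalues of the reversed definite pencil
`S_R v = η (S_L+μI) v`, λ = 1/η, with η at the numerical-rank level of
`S_R` treated as zero). Ridging the loss side rather than the constraint
side matters: `S_R` has an exactly zero labelled-target block in the
supervised and semisupervised systems, so the alternative ridge
`S_L p = λ(S_R+μI)p` manufactures a large eigenspace with numerator and
denominator both zero — exact λ=0 directions that crowd out every
informative one and drive the supervised variant to chance. With the ridge
on the loss side those directions get λ=∞ and drop out automatically.
Determinism: eigenvalues are sorted with stable tie order and each
eigenvector's sign is fixed so its largest-magnitude entry is positive,
making the supervised variant bitwise reproducible.

Degenerate settings (all objective weights zero) reduce to a ridge-only
pencil and still return finite projections — never NaN.

### Pseudo-label loop and final classification

Pseudo-labels start as the zero sentinel (all-zero one-hot rows), which
silences every target-involving MMD block on the first pass. Each iteration
trains the classifier on the projected labelled sets (source for MEKT;
source plus labelled target, each under its own projection block, for
ssMEKT) and re-predicts the unlabelled target under `P_T`. After the loop
the unlabelled-target projection is the block average — `(P_S+P_TL)/2` for
sMEKT, `(P_T+P_TL)/2` for ssMEKT — and the final score of the experiment is
computed on features projected that way. MEKT's final predictions are the
last iteration's pseudo-labels (transductive by construction).

## Classifier

Shrinkage LDA: class means plus a pooled within-class covariance shrunk
toward a scaled identity with the analytic Ledoit–Wolf intensity
(sklearn's estimator on the pooled class-centred residuals), equal priors,
`w = Σ̂^{−1}(m₁−m₂)`, boundary ties to class 1. When the within-class
residuals vanish entirely (singleton classes) the covariance falls back to
the shrinkage target itself, so the boundary is the perpendicular bisector.
A fixed intensity can be supplied; intensity 0 recovers classical LDA.

## Synthetic generator

Subject s observes class k through `A_s Σ_{k,i} A_sᵀ` where:

* the class prototypes `Σ₁, Σ₂` sit on a common geodesic, so their distance
  equals the `separation` dial exactly (separation 0 ⇒ identical classes ⇒
  chance-level decoding for every method);
* `A_s` is SPD with condition number capped at 10 (see the geometry note:
  the variability class alignment can actually undo);
* each subject deforms both prototypes by a common log-Gaussian
  perturbation of expected geodesic size `subject_spread` — the residual
  inter-subject shift that survives alignment, without which labelled
  target trials would carry no information beyond the source and the
  semisupervised variant could not outperform the unsupervised one;
* each trial jitters its covariance by a log-Gaussian perturbation of
  expected geodesic size `within_class_spread` — trial-to-trial
  non-stationarity, without which covariance-estimation error is the only
  within-class scatter and a 10-trial classifier is already perfect.

Trial samples are Gaussian given the trial covariance; optional additive
white sensor noise is off by default. Defaults — 5 subjects, 8 channels,
100 trials/class/subject, 200 samples/trial (two seconds at 100 Hz, the
shorter of the two standard epoch windows), separation 1.0, within-class
spread 2.0, subject spread 1.2 — were calibrated once so that the study
reproduces the accuracy regime of published motor-imagery transfer results
(no-transfer baseline in the low 0.8s, transfer variants in the low 0.9s,
semisupervised at or slightly above unsupervised) and then frozen.

What the generator does *not* emulate: realistic volume conduction or
montage geometry, non-Gaussian/heavy-tailed activity, artifacts, band
structure (trials are white within the trial covariance), or session
effects. Passing tests therefore demonstrate that the algorithms recover
transfer structure of the congruence-plus-deformation form, not that they
reach any particular accuracy on real EEG.

## Experiment protocol

Leave-one-subject-out and transductive: each subject in turn is the target,
the others are concatenated (after per-subject alignment) into the source.
Target trials are partitioned into a labelled portion — drawn balanced per
class, the count sweeping 10–50 in steps of 10 in the full protocol — and
an unlabelled portion that participates in adaptation (where the variant
uses it) and is scored. Repetition r partitions with seed + r, so results
are bitwise reproducible given the seed. True labels of the unlabelled
portion are used only at final scoring; the partition handed to the
adaptation code is stripped of labels, and the fit functions reject
labelled input in unlabelled positions.

The `baseline` variant is a no-transfer shrinkage LDA trained on the
labelled target tangent features alone — the reference every transfer
variant is compared against.

The transfer-recovery study (`transfer_study`, also behind
`scripts/acceptance.py`) runs 20 independently generated datasets with all
five subjects rotated in as targets (100 paired evaluations per variant)
plus a 20-dataset zero-separation control; at the frozen defaults this
takes well under a minute. Band-pass presets: Butterworth order 5 and FIR
order 50, both 8–30 Hz, applied forward-backward (zero phase) by default
since phase handling is a free choice; epoch windows 0.5–2.5 s and
0.5–3.5 s at 100 Hz. The shipped 25- and 29-channel sensorimotor montage
presets are approximate reconstructions from standard 10-20/10-10 labels.

## Known limitations

* sMEKT's labelled-target block is constrained only through the MMD
  coupling (its constraint block is zero as formulated), so beyond the
  first few eigenvectors its projection directions are regularization-
  dominated; the variant is correspondingly the weakest of the three here,
  as it is on one of the two published datasets.
* The semisupervised gain over the unsupervised variant is small at the
  default conditions (≈0.2 %, mirroring the published sub-percent edge at
  the matching labelled/unlabelled ratio) and is a mean-over-studies
  statement, not per-study dominance.
* Binary classification only; multi-class extensions are out of scope.
* Real-data readers (HDF5 container, BCI-competition MAT layout) are
  provided but no public-dataset results ship with the package.
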