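# Methods

## Model

`fragside` relates two binary views of the same n drugs: an n×p fingerprint
matrix X (columns = predefined chemical fragments) and an n×q adverse-event
matrix Y (columns = side-effect keywords). Both are column-centered and
scaled on training rows. Canonical correlation analysis seeks weight vectors
α, β maximizing the Pearson correlation ρ between the canonical components
u = Xα and v = Yβ. Two simplifications define the estimator:

* **Diagonal covariance.** The within-set covariances XᵀX and YᵀY are
  replaced by identity. This is the usual remedy when p, q ≥ n (the ordinary
  CCA weights are then not unique) and reduces the problem to the SVD of the
  p×q cross-product Z = XᵀY. `occa_fit` is exactly this truncated SVD.
* **Sparsity.** `scca_fit` adds L1 budgets ‖α‖₁ ≤ c₁√p, ‖β‖₁ ≤ c₂√q with
  c₁, c₂ ∈ (0, 1]. A unit-norm d-vector has L1 norm in [1, √d], so c
  interpolates from maximally sparse (budget 1, a single nonzero) to
  unconstrained (budget √d). When c·√dim < 1 — possible at small dimension —
  the budget is clamped to 1, the single-nonzero limit.

Each sparse component solves the penalized rank-1 matrix decomposition

maximize αᵀZβ s.t. ‖α‖₂ ≤ 1, ‖β‖₂ ≤ 1, ‖α‖₁ ≤ c₁√p, ‖β‖₁ ≤ c₂√q

by alternating closed-form updates: with β fixed, α ∝ S(Zβ, δ₁) where S is
soft-thresholding and δ₁ is the smallest threshold meeting the L1 budget
after renormalization (found by bisection to 1e-10; δ = 0 when the budget is
already met). Components k = 2…m come from deflation Z⁽ᵏ⁺¹⁾ = Z⁽ᵏ⁾ −
d_k α_k β_kᵀ with d_k = α_kᵀ Z⁽ᵏ⁾ β_k, which makes the reconstruction
identity Σ_k d_k α_k β_kᵀ + Z⁽ᵐ⁺¹⁾ = Z⁽¹⁾ hold to round-off (d_k equals the
singular value only in the unconstrained case). Signs are normalized so each
α_k's largest-magnitude weight is positive, flipping (α_k, β_k) as a pair —
this preserves αᵀZβ and ρ; ties break to the earliest index. ρ_k is the
Pearson correlation of Xα_k and Yβ_k on training rows after sign adjustment.

### Multi-start solver

Under active L1 constraints the alternating scheme is only locally
convergent, and a single SVD-based start measurably misses the global
optimum on small dense matrices (we observed a 3% objective shortfall
against a 10⁵-point feasible-region search). Each rank-1 solve therefore
runs from the leading right singular vector of the current Z⁽ᵏ⁾ (or a seeded
Gaussian when `init="random"`) *plus* axis-aligned starts on the 8 heaviest
columns of Z⁽ᵏ⁾, and keeps the iterate with the best objective. All starts
are deterministic given the parameters. Convergence: max-norm change of
(α, β) below `tol` (default 1e-7), cap `max_iter = 200`; a non-converged
best start is returned with a logged warning.

### Significance

Canonical correlations are tested by row permutation: shuffle the rows of
the normalized Y, refit the first component, and report the add-one
estimator p = (1 + #{ρ* ≥ ρ_obs}) / (1 + n_perm). This is a pragmatic
assessment of "is there any cross-matrix structure", not an exact test for
components beyond the first.

## Prediction

For a query fingerprint x, normalized to x̃ with the training statistics:

* **Profile estimate (`pinv`)** — ŷ = pinv(Bᵀ) Aᵀ x̃, the least-squares
  reconstruction of the side-effect profile whose canonical components match
  the query's; de-normalized per column with the training mean/sd. The
  pseudo-inverse truncates singular values below 1e-10 of the largest, since
  B is rank-deficient under strong sparsity.
* **Weighted score (`weighted`, default)** — s(x) = B Λ Aᵀ x̃ with
  Λ = diag(ρ). Used for ranking only and deliberately *not* de-normalized:
  a per-column affine map would not change per-side-effect ROC but would
  reshuffle the pooled global ranking.

The two predictors rank side-effects nearly identically when Y's columns
have homogeneous prevalence and the canonical correlations are uniform; with
heterogeneous prevalences the de-normalization offsets in ŷ reorder
rankings, and agreement degrades (Spearman ~0.8 on the two-block planted
benchmark vs >0.9 under homogeneous planting). This is a real difference
between the estimators, not a defect.

Zero-variance training columns (a fragment absent from, or present in, every
training drug) are centered, given a substituted sd of 1, and forced to zero
in the normalized representation, so they are inert in fitting and
prediction while keeping matrix shapes stable across CV folds.

## Baselines

* **Random** — each test drug receives, per side-effect, a hard 1 with the
  label's training prevalence f_j (a `prevalence` mode emits f_j itself for
  diagnostics; the hard mode yields a one-threshold ROC).
* **Nearest neighbour** — score k′/k: the fraction of the k most
  fingerprint-similar training drugs carrying the side-effect. Similarity is
  Tanimoto/Jaccard by default (the cheminformatics standard for bit
  vectors); ties at the k-boundary resolve by ascending training-row order.
* **SVM** — one classifier per side-effect (scikit-learn SVC, solver
  tolerance 1e-7), RBF kernel k(x, x′) = exp(−‖x−x′‖²/(2σ²)) with σ the
  width parameter; scores are signed decision values. Labels with a single
  training class get that class's constant value.

## Evaluation protocol

Drugs are dealt round-robin from a seeded permutation into K folds (sizes
differ by at most 1); the same assignment is shared across methods. Per
fold, normalizers and models see training rows only. Scores are pooled over
folds into the original row order, giving a fold-order-independent report:

* **Global AUC** — all n·q drug×side-effect pairs pooled into one ROC.
* **Per-label AUC** — columns lacking both classes are reported missing and
  excluded (not zero-filled) from means, avoiding prevalence artifacts.
* **Top-k accuracy** — per drug, the fraction of its k highest-scoring
  side-effects that are recorded; ties break by label index (stable sort).

AUC uses the rank (Mann–Whitney) statistic with average ranks, so tied
positive–negative pairs count 1/2 — identical to trapezoidal ROC
integration but with a simpler exhaustive-counting oracle.

## Synthetic data

`generate_planted_dataset` plants latent components — a set of fragment
columns and a set of side-effect columns that co-occur on a random drug
subset — into independent Bernoulli background. Defaults model the regime
the method targets: 2 components, 5-column supports on each side, carrier
fraction 0.2, flip noise 0.05 on planted bits, background rate 0.05
elsewhere, n = 500, p = 50, q = 40. Flip noise touches only planted cells
and background noise only unplanted cells, keeping the generative roles
separable. `generate_null_dataset` draws X and Y i.i.d. Bernoulli with no
cross-structure, for calibration.

What the generator does *not* emulate: the long-tailed prevalence
distribution of real side-effect vocabularies, correlated fingerprint bits
within a molecule, and drugs sharing protein targets but not fragments.
Passing tests therefore demonstrate the estimator's mechanics (recovery,
calibration, constraint satisfaction), not clinical performance.

### The noise ceiling on pooled AUC

Under the default planted conditions about half of Y's positive cells are
background noise, independent of X by construction. A Bayes-oracle scorer
given the exact ground truth achieves pooled global AUC ≈ 0.75 (≈ fraction
of predictable positives + half the rest); the fitted SCCA predictor reaches
the same value. Pooled AUC on this benchmark is thus capped near 0.75 no
matter how good the method is — a property of the noise model, worth keeping
in mind when reading absolute AUC values on synthetic data.

## Problem sizes and determinism

Tests and the acceptance script run at n ≤ 2000, p ≤ 50, q ≤ 40, with 20
repetitions for Monte-Carlo calibration and 49–99 permutations for p-values
— sizes chosen so the full statistical battery completes in minutes on one
CPU while keeping binomial error bands narrow enough for the stated
tolerances. Every stochastic step takes an explicit seed; the CLI derives
named substreams (split, init, permutation, simulation) from one top-level
seed so no stage's draws can silently shift another's.

## Known limitations

* c₁, c₂ and m are taken as given; the only built-in selection signal is CV
  AUC through the evaluation module.
* The permutation test refits only the first component; deeper components'
  p-values are approximations.
* Deflation does not enforce orthogonality between components; strongly
  overlapping supports can split one latent factor across components.
* The Random baseline's hard 0/1 scores give a single-threshold ROC; its
  AUC is accordingly coarse.
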