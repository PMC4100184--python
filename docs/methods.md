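# Methods

## Models

### Distributions

The package works with five families, all evaluated in log space:

* **Beta(u, v)** on (0,1): `ln f = lnΓ(u+v) − lnΓ(u) − lnΓ(v) + (u−1)ln x + (v−1)ln(1−x)`,
  computed entirely through `gammaln` (never a ratio of raw gamma values).
* **Gamma(k, θ)**, shape/rate (mean k/θ).
* **von Mises–Fisher** on the unit sphere S^{K−1}:
  `f(x) = c_K(λ) exp(λ μᵀx)` with
  `c_K(λ) = λ^{K/2−1} / ((2π)^{K/2} I_{K/2−1}(λ))`.  The Bessel function is
  evaluated exponentially scaled (`ive`), so λ = 400 — a realistic
  concentration for tight spectral features — does not overflow.  At λ = 0
  the normalizer is the reciprocal surface area of the sphere.
* **Watson** for axial data (x and −x equivalent):
  `f(x) = Γ(p/2)/(2π^{p/2}) · ₁F₁(1/2, p/2, κ)^{-1} · exp(κ (μᵀx)²)`, κ of
  either sign.  Because the density depends on x only through (μᵀx)², the
  axial symmetry f(x) = f(−x) holds bitwise.  This is the standard Watson
  normalizer; it is the only form consistent with the uniform limit at
  κ → 0.
* **Kummer's function** ₁F₁(r, p, κ) is computed as a log-sum-exp over the
  ascending series (terms peak near j ≈ κ; the truncation point grows with
  κ and the implementation raises if the tail is not negligible).  Negative
  arguments go through the Kummer transformation
  ₁F₁(r,p,κ) = e^κ ₁F₁(p−r,p,−κ) so all accumulated terms stay positive.
  Accuracy was cross-checked against an independent implementation
  (`scipy.special.hyp1f1`) to ~1e−13 relative over |κ| ≤ 500.

Direction vectors are validated to unit norm at tolerance 1e−8 and
re-normalized; anything farther from the sphere is rejected rather than
silently fixed.

Sampling: vMF uses the Ulrich/Wood rejection scheme (beta-distributed
tangent proposal).  Watson exploits that s = (μᵀx)² has density
∝ s^{−1/2}(1−s)^{(p−3)/2} e^{κs}; s is drawn by rejection from
Beta(1/2, (p−1)/2) with the exponential tilt as the acceptance weight
(acceptance ~ 1/κ for large positive κ, which is fine at the desk scales
used here), and the tangent direction is uniform on the orthogonal
subsphere.

### BG-NMF

Generative model for a bounded P × T matrix X:

    A_pk ~ Gamma(μ0, α0),  B_pk ~ Gamma(ν0, β0),  H_kt ~ Gamma(ρ0, ζ0)
    X_pt ~ Beta(Σ_k A_pk H_kt, Σ_k B_pk H_kt)

Inference keeps independent gamma factors for every entry of A, B, H.  The
beta log-likelihood contains E[lnΓ(Σ A H + Σ B H) − lnΓ(Σ A H) − lnΓ(Σ B H)],
which has no closed form under gamma posteriors; it is replaced by a
first-order expansion at the current posterior means combined with a
Jensen split of ln(Σ_k A_pk H_kt) over components.  The resulting sweep has
closed-form shape/rate updates (with ᾱ = ĀH̄, β̄ = B̄H̄, Ψa = ψ(ᾱ+β̄) − ψ(ᾱ),
Ψb = ψ(ᾱ+β̄) − ψ(β̄)):

    shape(A) = μ0 + Ā ⊙ (Ψa H̄ᵀ)            rate(A) = α0 + (−ln X) H̄ᵀ
    shape(B) = ν0 + B̄ ⊙ (Ψb H̄ᵀ)            rate(B) = β0 + (−ln(1−X)) H̄ᵀ
    shape(H) = ρ0 + H̄ ⊙ (ĀᵀΨa + B̄ᵀΨb)      rate(H) = ζ0 + Āᵀ(−ln X) + B̄ᵀ(−ln(1−X))

All rates are positive by construction (ln X < 0).  Because the expansion
point moves every sweep, ascent of the recorded objective is not automatic;
each sweep therefore backtracks geometrically (step 1, 1/2, … 1/32) on the
**ELBO surrogate** — the beta log-likelihood at posterior means plus the
log-priors at posterior means — and stops if no step ascends.  The recorded
trace is consequently non-decreasing; a stop for lack of ascent is an
honest early termination, not a hidden failure.

The sparsity constraint on the excitation columns is realized as a
sub-unit gamma shape on H (ρ0 = 0.5 by default); with near-binary
excitations the reconstruction (ĀH̄) ⊘ (ĀH̄ + B̄H̄) is well approximated by
W̄H̄ with the bounded pseudo-basis W̄ = Ā ⊘ (Ā+B̄), which is what downstream
clustering consumes.

Defaults: priors (1,1) everywhere except ρ0 = 0.5; tol 1e−5 on the relative
surrogate change; max 500 sweeps; update order A → B → H.  Initialization:
per-row method-of-moments beta fits spread over the K components with
seeded multiplicative jitter, and random excitations scaled to unit column
sums.  Input entries must be inside [1e−6, 1−1e−6] (the shared clipping
constant, applied by the file reader).

### Mixture models

All variational fits share: sparse Dirichlet prior on the weights
(concentration 1e−3), seeded k-means initialization, convergence at 1e−6
relative change of the surrogate or 500 iterations, pruning of components
with posterior weight < 0.01 after convergence followed by one refit pass.
Each fit records a surrogate trace (mixture log-likelihood at posterior
means plus parameter log-priors); an iteration that would lower it is
rejected and the fit stops, so the recorded trace is monotone by
construction.  After pruning, the refit's trace is reported (the pruned
model is a different model; its trace is not comparable to the pre-prune
one).

* **VBBMM** — independent beta per dimension, gamma posteriors over the
  shapes with the same first-order bound as BG-NMF:
  shape ← a0 + N_m · ū[ψ(ū+v̄) − ψ(ū)], rate ← b0 − Σ_n r_nm ln x_nk.  The
  shape prior Gamma(1, 0.5) (prior mean 2) matters: a starved component
  reverts to a broad Beta(2,2), keeps losing responsibility, and dies —
  this is what lets an M_init = 15 fit collapse to the true component
  count.  (A prior with a large mean makes starved components *sharper*,
  which blocks the collapse; that failure mode was observed and is the
  reason for this default.)
* **VBvMM** — closed-form mean directions from responsibility-weighted
  resultants; concentration from the Banerjee-initialized Newton solve of
  A_K(λ) = r̄ − b0/N_m, where the gamma-prior rate b0 = 1 shrinks weakly
  supported concentrations.  b0 = 1 is also what makes a fit on uniform
  sphere data flatten and prune its components instead of freezing into a
  patchwork of tight local components (a genuine local optimum observed
  with weaker priors).
* **VBWMM** — axial: component axis = top eigenvector of the
  responsibility-weighted scatter, concentration from a bisection solve of
  d/dκ ln ₁F₁(1/2, p/2, κ) = r̄ through the log-space Kummer evaluations.
  Estimation is restricted to κ > 0 (clusters around axes); the girdle
  form remains available in the distributions module.  Initialization is
  an in-house *axial* k-means (assignment by (aᵀx)², axis update by top
  eigenvector), since Euclidean k-means is meaningless under sign
  ambiguity.  Label assignments are exactly invariant to flipping the sign
  of any input row.
* **VBGMM** — the Gaussian baseline is backed by
  `sklearn.mixture.BayesianGaussianMixture` (sparse Dirichlet weights,
  `mean_precision_prior = 10` so starved components collapse onto the data
  mean and die; with the sklearn default a single Gaussian was left split
  in two).  sklearn exposes only the final lower bound, so this family's
  trace has a single entry.
* **RPBMM** — recursive binary partitioning: at each node a 1-component
  and a 2-component independent-beta model are fitted (weighted maximum
  likelihood via damped Newton on the digamma moment conditions; weighted
  EM for the pair), and the node splits iff the responsibility-weighted
  BIC improves: wtdBIC = −2·Σ w_n ln f(x_n) + d·ln(Σ w_n) with d the free
  parameter count.  Child weights are w_n·r_nc; child membership is the
  hard argmax; the heavier child is labelled "L".  Leaves are final
  clusters labelled by their split path ("r", "rL", "rLR", …).

### Embeddings

* **Top-variance selection** keeps the n highest-variance rows, original
  order preserved, ties toward earlier rows.
* **RMT dimension** — rows standardized, eigenvalues of the T × T
  sample-sample correlation matrix C = X̃ᵀX̃/P compared against the
  Marchenko–Pastur upper edge.  At finite size the top noise eigenvalue
  fluctuates around the asymptotic edge (1+√(T/P))² on the Tracy–Widom
  scale and crosses it in a nonnegligible fraction of pure-noise runs, so
  the working threshold is the finite-sample (Johnstone) centering plus
  three Tracy–Widom scale units.  This keeps the false-positive rate on
  1000×100 noise at ~1% while leaving genuine signal components — which
  sit far above the bulk — uncounted only if they are weaker than the bulk
  fluctuation itself.
* **PCA** — scores on the K leading eigenvectors of the feature
  covariance (rows mean-centered, no variance scaling), via thin SVD with
  each eigenvector's sign fixed so its largest-magnitude entry is positive
  (backend-independent reproducibility).
* **Spectral embedding** — Gaussian affinity A_ij = exp(−‖x_i−x_j‖²/(2σ²))
  with zero diagonal, M = D^{−1/2} A D^{−1/2}, top-K eigenvectors as rows
  of Y, columns normalized to unit l2 norm.  The automatic bandwidth is
  σ = sqrt(Var(B)) where B is the matrix of squared pairwise distances —
  the variance is taken over all N² entries including the zero diagonal
  (the convention is stated here because either choice is defensible; the
  diagonal adds N known zeros out of N², a vanishing perturbation at the
  cohort sizes targeted).  Isolated samples (zero affinity row sum) raise
  an error naming the sample rather than producing NaNs.

### Scoring

Each cluster maps to the truth class holding the majority of its members,
ties broken toward the larger class; a sample is misclustered iff its own
class differs from its cluster's majority class.  The error rate is
100 × misclustered / N.  For binary truth the two directions are reported
separately with class1 = the larger class (cancer in a typical cohort);
for more than two classes only the confusion table and the error rate are
meaningful.  The identity error_rate = 100 × (c→n + n→c)/N holds exactly
by construction.

Pipelines enforce the geometry-compatibility matrix: bounded-support
clusterers (vbbmm, rpbmm) require the BG-NMF pseudo-basis, directional
clusterers (vbvmm, vbwmm) require the spectral embedding, and the Gaussian
baseline pairs with PCA.

## Synthetic data

`gen_group_methylation` emulates a methylation cohort of T samples in one
normal group plus several cancer subgroups (default 23 + 40/40/33 = 136,
the shape of a typical 27k breast cohort), P CpGs (default 1000 at desk
scale; 5000 matches a full top-variance selection), a fraction of
differentially methylated CpGs (default 0.2) whose group means shift by
±delta (default 0.3) with group-specific signs, and per-entry beta noise
at a common concentration (default 60, i.e. a per-entry standard deviation
of roughly 0.05–0.06).  What it does **not** model: probe-chemistry
effects (type I/II), batch effects, missingness, spatial CpG correlation,
or cell-type mixtures.  Passing tests therefore demonstrate correctness of
the algorithms under the stated generative assumptions, not performance on
any real cohort.

`gen_bgnmf_matrix` draws exactly from the BG-NMF generative model and
records the true mean matrix; `gen_directional_mixture` places component
axes as a randomly rotated orthonormal set (pairwise 90°, satisfying the
≥60° separation contract) and samples through the distribution module's
samplers.  Every generator is a pure function of its parameter record;
regeneration is bitwise identical.

## Numerical choices and edge cases

* Shared clipping constant 1e−6 for beta-values (single source of truth in
  `bgnmf.EPS`); exact 0/1 in input files is clipped with a logged count,
  anything outside [0,1] is an error naming the cell.
* ₁F₁ series truncation raises rather than returning a silently truncated
  value; Bessel evaluations are exponentially scaled throughout.
* Beta ML fits clip shapes to [1e−3, 1e6]; concentration solves are capped
  (λ ≤ 1e5, κ ≤ 2000) — beyond those values the likelihood is flat to
  machine precision at the sample sizes involved.
* Degenerate inputs: constant rows are dropped (with a warning) before RMT;
  k-means ties and eigenvector signs are fixed deterministically; all fits
  are deterministic given their seed.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full suite completes in minutes while every statistical claim is still
well-powered: BG-NMF recovery at P=200, T=60, K=3 over 5 seeds; mixtures
at n=200–300 observations; RMT at 1000×100 over 100 seeds; the end-to-end
pipeline at P=1000, T=136 (the full cohort profile).  The full-array
P=5000 selection is exercised only as a shape contract.

## Known limitations

* The BG-NMF bound is first-order; its fixed point is close to, but not
  exactly, the optimum of the intractable ELBO.  Recovery correlation
  ~0.97 on generative draws reflects that (plus identifiability limits of
  the factorization itself).
* Weight-collapse pruning depends on the breadth of the parameter priors
  (documented defaults above); highly imbalanced tiny clusters near the
  prune threshold (weight ≈ 0.01) can be removed.
* VBWMM fits only bipolar (κ > 0) components; girdle-distributed clusters
  would need the κ < 0 branch wired into the mixture.
* The RMT threshold assumes independent noise entries after
  standardization; strong row correlation inflates K.
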