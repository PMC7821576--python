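# Methods

## Model

Subject `i` contributes a multivariate time series. At the voxel level
`Y_i ∈ R^{T_i×V}` is assumed low-rank, `Y_i = A_i S`, with `S ∈ R^{K×V}`
spatial components shared across subjects and `A_i ∈ R^{T_i×K}` the
subject's mixing (component time-course) matrix. Rows of `A_i` are modelled
as i.i.d. `N(0, Σ_i)` with eigendecomposition `Σ_i = Γ_i Λ_i Γ_iᵀ`. The
covariance-regression assumption is that R of the K eigenvectors are common
across subjects, `Γ = (γ_1, …, γ_R)`, and that their eigenvalues follow a
log-linear model in the covariates, `log λ_ic = x_iᵀ β_c`. Equivalently the
projected score `z_itc = γ_cᵀ a_it` is mean-zero Gaussian with variance
`exp(x_iᵀ β_c)`: a heteroscedastic variance regression. Rows within a
series are treated as exchangeable; temporal autocorrelation is not
modelled.

Up to constants, the negative log-likelihood for a single projection is

    l(γ, β) = ½ Σ_i T_i [ x_iᵀβ + exp(−x_iᵀβ) · γᵀ Σ̂_i γ ],

where `Σ̂_i` is the subject's sample covariance (column-centered, divisor
`T_i`, consistent with the likelihood even though the model is mean-zero).

## Estimation

**β-step.** For fixed `γ` the problem is a gamma-family log-link fit of the
responses `s_i = γᵀ Σ̂_i γ` with weights `T_i`. It is solved by Newton–
Raphson with step halving; the objective is convex in β (Hessian
`½ Xᵀ diag(T_i e^{−η_i} s_i) X`). Convergence is declared when the gradient
norm falls below `tol · ΣT_i` (default `tol = 1e−10`); a rounding-tolerant
acceptance test and a step-size floor prevent stalls at machine precision.

**γ-step.** For fixed β, minimizing `γᵀ M γ` with
`M = Σ_i T_i e^{−x_iᵀβ} Σ̂_i` requires a normalization: under a plain unit
norm the profile objective is flat (any rescaling of γ is absorbed by the
intercept). We therefore constrain `γᵀ H γ = 1` with `H` the pooled
weighted covariance `Σ T_i Σ̂_i / Σ T_i`, plus H-orthogonality to
previously extracted components. The solution is the bottom eigenvector of
the generalized eigenproblem restricted to the constraint-complement
subspace (null space of `(HΓ_prev)ᵀ`).

Both steps weakly decrease the objective, so the alternation is monotone
(asserted at run time). The final `γ` is rescaled to unit Euclidean norm —
matching the orthonormal-eigenvector convention of the model — with the
intercept corrected by the log of the squared rescaling factor, and
sign-canonicalized (largest-magnitude loading positive, ties resolved at
the lowest index). Signs are not identifiable, in either the ICA or the
CAP stage; all comparisons in tests use |cos angle| or absolute
correlations.

Components are extracted sequentially (greedily) rather than by joint
R-component optimization: each solve stays a clean eigenproblem and the
accumulated constraints mirror the "R common columns" structure of the
model. Initializations are the K eigenvectors of `H` plus random unit
vectors up to `n_restarts = K + 5`; the best final objective wins.
Alternation stops at relative objective change `< 1e−8` (default), capped
at 500 iterations. Every subject must satisfy `T_i > K` (no shrinkage
covariance estimator is provided).

## Model order: deviation from diagonality

For a candidate set of columns `Γ`, `Λ̂_i = Γᵀ Σ̂_i Γ` and

    DfD(Γ) = Π_i [ det(diag Λ̂_i) / det Λ̂_i ]^{T_i/ΣT_i} .

By Hadamard's inequality each factor is ≥ 1, with equality iff `Λ̂_i` is
diagonal, so DfD = 1 exactly when `Γ` co-diagonalizes every subject
covariance. The trace is computed after each sequential extraction
(evaluated on the R fitted columns; completing `Γ` to a full K×K basis is a
noted alternative that is not implemented). The selection rule keeps the
largest r whose DfD stays below an absolute threshold τ (default 2) and
whose relative jump from r−1 stays below 1+δ (default 0.5); both are
configuration parameters because the underlying criterion is a visual
heuristic ("stop before the metric leaves 1 or jumps"). When no r
qualifies the order falls back to 1 with a warning.

Per-subject variance explained by component c is
`100 · γ_cᵀ Σ̂_i γ_c / tr(Σ̂_i)` (unit-norm γ); the summary table averages
over all subjects and over gender × alcohol cells. The quadratic-form/trace
ratio is this package's construction for that summary.

## Inference

Confidence intervals come from a subject-level bootstrap: subjects
(covariance and covariate row jointly) are resampled with replacement,
β is re-estimated for each fixed fitted column of `Γ̂`, and percentile
intervals are read off the bootstrap distribution (default B = 500,
α = 0.05). Endpoints are order statistics — the ⌈αB/2⌉-th and
⌈(1−α/2)B⌉-th sorted draws — so B = 1 degenerates to a point. `Γ̂` is
never re-estimated inside the bootstrap; re-running the γ search per
replicate is out of scope. Resamples with a rank-deficient design (a
binary covariate constant in the draw) are redrawn and counted. The four
reported contrasts of the gender × alcohol interaction are
`β_g`, `β_g+β_ga`, `β_a`, `β_a+β_ga`. No multiplicity correction is applied
across components. The same machinery transfers fitted projections to
held-out sessions (`transfer_projection`), where only the covariances are
recomputed.

## Edge-wise baseline and the special case

The comparator computes Pearson correlations for all K(K−1)/2 component
pairs, Fisher-z-transforms them (`z = arctanh r`), and fits one OLS model
per edge with two-sided t-tests for coefficients and contrasts;
Benjamini–Hochberg adjustment runs within each coefficient/contrast family
across edges (pooling across families is available as a configuration).
Edges with any raw contrast p < 0.05 are flagged for display.

With standardized unit-variance series and the fixed projection
`ω = (1/√2, 1/√2, 0, …)` on a pair (j,k), the CAP response is
`ωᵀ Σ̂ ω = 1 + r̂_jk`, and since `log(1+r) ≈ ½ log((1+r)/(1−r))` for small
r, the CAP log-linear fit approximately reproduces the pairwise Fisher-z
regression. The weight 1/√2 (not 1/2) is forced by the unit-norm
convention and by the variance identity `Var(ωᵀy) = 1 + φ_jk`. The
approximation degrades at large |r|, which the validation study reports
but does not assert against.

## Dimension reduction

Voxel series are standardized per column (sample sd, ddof 1; zero-variance
columns raise an error naming the offending indices), optionally pre-reduced
per subject to `min(T_i−1, 2K)` temporal dimensions (an exact full-memory
two-stage PCA stands in for incremental group-PCA variants used on
large cohorts), temporally concatenated, and reduced to the top-K spatial
principal directions. Spatial ICA treats voxels as samples: the
PC coordinates are explicitly centered and whitened by SVD (the explicit
projection keeps the whitened covariance exactly identity even when the
coordinate variances are tiny and nearly equal, a regime where generic
whitening code can misbehave), and the fixed-point log-cosh negentropy
algorithm with symmetric decorrelation runs from 5 seeded restarts,
keeping the solution with the largest negentropy proxy. Estimated maps get
unit row norms and positive skewness. Non-convergence within `max_iter` is
a recorded warning, not an error, and the partial result is returned;
Gaussian sources are returned as an orthonormal-in-whitened-space basis
with no recovery claim. Dual regression recovers subject time courses as
the least-squares solution of `Y_i ≈ A_i S`.

K defaults to 25 components, a standard dimensionality for whole-brain
component analyses, and is fully configurable.

## Synthetic data generator

The generator realizes the model exactly, so every downstream stage can be
validated against ground truth:

- **Covariates:** intercept, centered Gaussian age (defaults mean 29.0,
  sd 3.4), gender and alcohol indicators and their product, with cell sizes
  (27, 40, 14, 28) for (female nondrinker, male nondrinker, female drinker,
  male drinker) — a 109-subject cohort layout typical of medium
  single-site studies.
- **True model:** `Γ` is the first R columns of a Haar-uniform orthogonal
  matrix; default β templates carry effect magnitudes ≈ 0.3–0.5, which
  gives realistic power at n ≈ 109.
- **Mixing series:** per subject, the non-common eigenvectors `U_i` are a
  fresh random orthonormal completion of `Γ` (only the R columns are
  shared); non-common eigenvalues are log-uniform on [log 0.5, log 2],
  drawn per subject and constant over time, so the common components are
  neither systematically largest nor smallest. Rows are exact draws from
  `N(0, Γ_i Λ_i Γ_iᵀ)`.
- **Spatial maps:** independent Laplace rows with a focal fraction
  (`sparsity`) at unit amplitude and the rest at 5% background amplitude,
  unit row norm. The two-scale mixture keeps every voxel active (exact
  zeros would leave most voxel columns constant at small sparsity) while
  remaining strongly super-Gaussian, which is what negentropy ICA needs.
- **Voxel data:** `Y_i = A_i S` plus optional i.i.d. Gaussian noise.

All generators are pure functions of their seeds.

What the generator does **not** emulate: temporal autocorrelation and
hemodynamics, spatial autocorrelation of noise, scanner artifacts,
registration error, or inhomogeneous voxel variances beyond what the maps
induce. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to real-fMRI violations
of them.

A note on standardization: per-voxel unit-variance scaling (enforcing the
model's equal-variance assumption, as done on real data) rescales the
generative maps to `S·D⁻¹` and destroys their independence and
super-Gaussianity, so the exact noise-free recovery analyses run the
reduction with `standardize=False`; the pipeline default remains `True`.

## Validation studies and problem sizes

`icacap.validation` packages the numerical experiments used by the test
suite and the acceptance script. Chosen sizes: parameter recovery at
K=6, R=1, n=100, T=200 over 50 replicates (median |cos angle| and median
max-norm β error); bootstrap coverage at B=200 over 200 replications of
four contrasts (800 intervals) with the true projection held fixed —
fixing γ isolates the interval construction, which conditions on `Γ̂` by
design; FDR on 1000 uniform-null simulations of 100 tests; the special
case at n=200, T=500 with |φ| ≤ ~0.1 over 50 replicates; noise-free
reduction recovery at K=5, V=2000, 8 subjects, T=300. These sizes complete
in well under a minute each on one CPU while leaving the Monte-Carlo error
small relative to the tolerances checked.

## Known limitations

- The multistage fit (ICA, then CAP) loses efficiency relative to a joint
  likelihood; a unified model is out of scope.
- No statistical significance is attached to reconstructed voxel maps; the
  display threshold (|standardized value| > 2) is a presentation choice.
- Percentile intervals are the plain variant (no BCa or studentization);
  no analytic standard errors are provided.
- The DfD rule's defaults (τ = 2, δ = 0.5) formalize a visual heuristic and
  should be inspected alongside the trace, not trusted blindly.
- Components have no per-subject index permutation: the R shared
  eigenvectors are assumed to be the same R directions for everyone.
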