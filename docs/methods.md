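# Methods

This note records the model, the numerical choices, and the design
decisions behind `ckalign`, at the level of detail a maintainer or a
methodologically careful user needs. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Model and objective

Given N labeled samples, two N×N kernels describe the data: a Gaussian
kernel on linearly projected features, parameterized by a projection
W ∈ ℝ^(P×d) and bandwidth σ > 0, and a class-indicator (delta) label
kernel. The empirical centered kernel alignment

ρ̂ = ⟨K̄_X, K̄_L⟩_F / √(⟨K̄_X, K̄_X⟩_F ⟨K̄_L, K̄_L⟩_F)

lies in [0, 1] by Cauchy–Schwarz; with the delta label kernel it is an
HSIC-style class-separability score. The learning problem is
min_W −log ρ̂. The additive constant ½·log⟨K̄_L, K̄_L⟩_F does not depend
on W and is dropped. The form of the label kernel is a design choice
(nothing forces the delta kernel); `cka` also accepts arbitrary
precomputed kernels so other label similarities can be swapped in.

Two equivalent computational routes exist for each inner product — the
trace form tr(K_X H K_L H) and the centered-Frobenius form — and the suite
asserts their agreement to 1e−10 on random matrices; the production path
centers once and takes elementwise products.

### Gradient

The double-centering map is self-adjoint and idempotent, so with
u = ⟨K̄_X, K̄_L⟩ and v = ⟨K̄_X, K̄_X⟩ the kernel-space gradient of the cost
is G = −K̄_L/u + K̄_X/v. For the Gaussian kernel, writing S = G ∘ K and
L = diag(S1) − S (a graph Laplacian; diagonal terms cancel because
self-distances are zero), the chain rule collapses to

∂cost/∂W = −(2/σ²) Xᵀ L X W,

and for a saturated layer H = ϑ(H₀W): ∂cost/∂H = −(2/σ²) L H followed by
standard backprop through ϑ′. Both paths are permanently guarded by
central-finite-difference tests (relative tolerance 1e−4); the linear
gradient is also checked to be orthogonal to the rotation symmetry
direction (the cost depends on W only through WWᵀ).

### Numerical floors and degeneracies

ρ̂ is clipped below at 1e−12 before the log so the cost stays finite if an
iterate momentarily has non-positive alignment. A centered kernel whose
squared Frobenius norm falls below (1e−14·N)² is treated as degenerate and
raises an error naming the likely cause (constant kernel → re-tune σ;
single class → no supervised signal). Single-class label input raises
immediately when the label kernel is built.

## Optimization

Default: full-batch gradient descent with a backtracking (Armijo) line
search, sufficient-decrease constant 1e−4. Each search starts at
min(4 × last accepted step, initial rate), so a transient collapse of the
step size cannot persist as a slow crawl. Accepted costs are therefore
non-increasing by construction — asserted on every fit in the tests — and
the final alignment is never below the alignment at initialization.
Convergence: relative cost change below `tolerance` (default 1e−6), or no
admissible descent step above 1e−15. Hitting `max_iters` (default 200)
marks the model `converged=False`; this is a warning status, not an error.

Minibatch SGD is available via `batch_size` (the stated optimizer of the
original formulation); each minibatch contributes the gradient of the
alignment computed on its own sub-kernel, the learning rate decays as
1/(1 + 0.1·epoch), and the full-batch cost is recorded once per epoch.
No monotonicity is guaranteed on this path, which is why full-batch is the
default.

Initialization is the top-d principal directions of the z-scored training
features (eigendecomposition of the covariance, descending eigenvalues,
sign fixed so each column's largest-magnitude entry is positive — fully
deterministic). No orthogonality constraint is imposed during descent; the
fitted span is generally not orthogonal.

### Standardization

Features are z-scored inside `fit_metric` / `pretrain_network` on the
training data, and the shift/scale is stored on the model so `transform`
applies it consistently. Rationale: the intended inputs mix mm³/mm²/mm
units, and both PCA initialization and the median-heuristic bandwidth are
meaningless across heterogeneous scales. The generator's scale-confounded
family exists precisely to exercise this: unstandardized PCA provably
picks the noise directions there (tested). Constant features get scale 1
and pass through.

### Bandwidth

The bandwidth-tuning procedure cited in the source literature is not
reproducible from the available description, so the default is a stand-in,
not a claimed equivalent: the median of the positive projected pairwise
Euclidean distances (excluding zeros, so duplicated samples do not shift
it). An alternative, selectable via `bandwidth_strategy="kernel-variance"`,
scans a log-spaced grid around the median for the σ maximizing the
variance of off-diagonal kernel entries. σ is tuned once at
initialization and then held fixed during descent, which keeps the
optimized objective well-defined (re-tuning mid-run changes the cost
surface and would break the monotonicity contract).

### Target dimension

Default d = min(P, 3C). Alignment with a C-class delta kernel needs only
low rank, but a few extra dimensions ease the nonconvex optimization;
anything in [C, P−1] is configurable.

## Layer-wise pretraining

Hidden layers use ϑ(z) = (tanh z + 1)/2. For m = 1…M−1 sequentially:
initialize W^m from the PCA of the previous representation (padded with
small seeded Gaussian columns when the requested width exceeds the
available rank), tune σ_m on the initialized saturated representation,
then maximize ρ̂ between the Gaussian kernel on ϑ(H^(m−1)W^m) and the
label kernel. Offsets b^m are fixed at zero during pretraining and become
trainable in fine-tuning; earlier layers are frozen once fitted. The
output (softmax) layer is randomly initialized — it has no alignment
objective and is learned only by fine-tuning. With the identity activation
and a single hidden layer the procedure reduces exactly to the linear
metric fit (same trajectory under the same seed; tested).

A structural caveat the tests exploit: with zero offsets a single
saturated layer is an odd map composed with ϑ, so XOR-type geometry
(samples at ±u, ±v with labels by sign product) cannot be untangled in
one layer — x and −x always land at complementary activations. A second
hidden layer breaks the symmetry because its inputs live in (0,1), whose
mean acts as an implicit offset. This is why the XOR checks use two hidden
layers, and why single-hidden-layer pretraining on XOR-like data is
expected to plateau at modest alignment.

Saturated representations lie in (0,1) (inclusive at float precision), so
layer-m pairwise distances are bounded by √Q_m and the per-layer median
bandwidth respects that scale automatically.

## Classifiers

- **k-nn**, k ∈ {1, 3, 5, 7, 9}: Euclidean vote in the (optionally
  transformed) space. Vote ties break by smallest summed neighbor
  distance, then smallest class index — fixed here because the convention
  affects reproducibility and is otherwise arbitrary.
- **SVM**, C ∈ {0.1, 1, 10, 100, 1000}: scikit-learn's SMO-based `SVC` on
  a precomputed Gaussian kernel (the projected kernel when a metric is
  supplied), one-vs-one multi-class — the standard reduction for
  SMO-style solvers.
- **NN**: small in-package numpy MLP (sigmoid hidden layers, softmax
  output, mean cross-entropy), full-batch gradient descent with momentum
  (defaults 0.5/0.9). In-package because fine-tuning must start from the
  CKA-pretrained weight matrices, which external MLP implementations do
  not accept as initialization. Hidden sizes are grid-searched over
  log-spaced values in [C, P−1]. A non-finite loss or weight aborts with
  diagnostics.

Hyperparameters are selected by subject-grouped 5-fold CV (all scans of a
subject share a fold; every fold must contain every class, enforced), with
per-sample accuracy as the criterion and ties broken toward the simpler
model (smaller k/C/width). The outer evaluation uses a class-stratified
subject-level 70/30 split.

## Evaluation statistics

τ_c = t_c/N_c is within-class recall; overall accuracy is implemented as
(Σ_c t_c)/N, which equals the class-size-weighted mean of the τ_c — an
identity the tests assert on random confusions (the expectation-over-
classes form sometimes written for this quantity does not normalize and is
interpreted this way). std_τ is the ddof=1 standard deviation of the τ_c
in percent. CIs are percentile bootstrap over test indices (default
B = 1000, 95%); a resample missing a class required by the measure is
redrawn and the redraw count kept. The baseline-vs-enhanced comparison is
a one-sided Welch two-sample t-test ("enhanced exceeds baseline") at 1%;
two zero-variance samples with equal means give p = 1 by convention.
Per-class AUC is one-vs-rest, rank-based with mid-rank ties
(scikit-learn), checked against a pair-counting oracle.

## Synthetic generator

`GeneratorSpec` defaults mirror the intended application: three classes
with 231/379/286 subjects, 2–5 scans per subject (N ≈ 3,200), and 310
features — 6 signal columns plus FreeSurfer-like blocks (63+37
TIV-normalized volumes, 68 areas, 68+68 thickness statistics) at their
native scales. Class-conditional Gaussians with shared covariance in
signal space; outer class means sit ±separation/2 (default 3 within-class
SD — a strong but not trivial multivariate effect) along a diagonal
direction, and the middle class interpolates between them
(`intermediate_mix`, default 0.5), mimicking MCI as an intermediate stage.
Subjects get their own mean (between-subject SD 1.0) and scans add
within-subject noise (SD 0.5), so repeats correlate and subject-grouped CV
is meaningfully exercised. Nuisance features are label-independent
Gaussians with a subject-level offset.

What the generator does *not* emulate: correlated region measurements,
site/scanner effects, longitudinal progression, label noise, or class-
dependent covariance. Passing tests therefore demonstrate that the
machinery behaves as designed under its own assumptions, not that any
particular clinical accuracy is attainable.

Pinned fixtures: `tiny3class` (30×6 smoke instance), `xor2class`
(2 signal + 2 noise dims, 4-cluster XOR geometry), `scale-confounded`
(1 discriminative feature + 9 nuisance features at 100× scale). Each is
byte-reproducible from its seed.

## Problem sizes and runtime choices

The replicate studies (optimizer contract, feature recovery, classifier
improvement, pretraining value) use 20 seeded cohorts of the pinned
fixture families — large enough for the paired significance test, small
enough to run in seconds. The cohort-scale check runs one pipeline at the
full default shape (~3,200 scans × 310 features) with the k-nn family and
a 30-iteration metric-fit budget; at that scale each gradient step costs
O(N²P) and 30 steps already move ρ̂ well away from its PCA start.

## Known limitations

- The alignment objective is nonconvex; different seeds can reach
  different local optima. The contract is improvement over the PCA start,
  not global optimality.
- Bandwidth is fixed during descent; a poor initial σ can cap the
  achievable alignment (the degenerate-kernel error asks for re-tuning).
- Zero-offset pretraining cannot resolve odd-symmetric class geometry in
  a single layer (see above).
- The SGD path trades the monotonicity guarantee for speed and is not
  used by default.
- Bootstrap CIs are percentile-based and per-scan, not per-subject;
  repeated scans of a subject are treated as exchangeable test units, as
  in the evaluation scheme this package mirrors.
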