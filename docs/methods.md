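# Methods

## Model

The pipeline clusters `n` samples described by a non-negative feature
matrix `X` (rows = samples) by factorizing a normalized sample-similarity
graph. The stages and their operators:

1. **Adaptive Gaussian kernel.** `w_ij = exp(−‖x_i − x_j‖² / (σ_i σ_j))`,
   `i ≠ j`, with `σ_i` the Euclidean distance from sample `i` to its `d`-th
   nearest other sample. The diagonal is zero (no self-similarity).
   Adaptive bandwidths make the kernel scale-free per neighbourhood: dense
   regions get narrow kernels, sparse regions wide ones.
2. **kNN sparsification (OR rule).** `w_ij` is kept iff `i` is among the
   `p` most-similar samples of `j` or vice versa; the union rule preserves
   symmetry exactly. Neighbour ranking ties are broken by the lower sample
   index so the construction is deterministic.
3. **Normalization.** `A = D^{−1/2} W D^{−1/2}` over the sparsified `W`;
   this is the matrix that is factorized. Its spectrum lies in `[−1, 1]`.
4. **Laplacian penalty.** `L = D − P` with `P` the sparsified `W` — the
   same graph, unnormalized Laplacian form. `tr(Hᵀ L H) =
   ½ Σ_ij P_ij ‖h_i − h_j‖²` penalizes factor differences across edges
   (global smoothness).
5. **Vicus penalty.** For each sample `i`, its `K` most similar samples
   (from the *dense* kernel, pre-sparsification: the local neighbourhood
   size is a parameter of its own, independent of `p`) plus `i` form a
   subnetwork, ordered `[neighbours…, centre]`. With `S_i` the
   row-normalized restriction of `W` to these `K+1` nodes, the terminal
   label-diffusion operator is `(1 − α)(I − α S_i)^{−1}`; its centre row
   `β_i` is a probability vector, and the reconstruction weights of the
   centre from its neighbours are `β_i[j] / (1 − β_i[K+1])`. Stacking these
   rows gives `B` (row sums exactly 1, `K` nonzeros per row), and
   `V = (I − B)ᵀ (I − B)` — symmetric PSD with `V·1 = 0`, by construction a
   Gram matrix. `V` plays the same algebraic role as `L` but is built from
   local connectivity only.
6. **Factorization.** `min_{H≥0} ‖A − H Hᵀ‖_F² + α[tr(HᵀLH) + tr(HᵀVH)]`
   with rank `k` = requested cluster count. The two penalty weights are
   equal by default (separate weights would be a trivial extension; the
   shared `α` keeps the parameter space one-dimensional). Hard labels are
   the per-row argmax of `H`, ties to the lower column.

The four variants (`snmf`, `laplacian`, `vicus`, `lvsnmf`) differ only in
which penalty terms are active; with both off (or `α = 0`) every code path
reduces bit-identically to plain symmetric NMF.

## Solver

**Update rule.** With the sign split `V = V⁺ − V⁻` (`V⁺ = (|V|+V)/2`,
element-wise, exact in floating point) and `L = D − P`, the multiplicative
direction is

    ratio = (A H + α (P + V⁻) H) / (H Hᵀ H + α (D + V⁺) H)

All matrices in numerator and denominator are non-negative, so the update
preserves `H ≥ 0`, and `ratio = 1` exactly at stationary points.

The *undamped* update `h ← h · ratio` is not monotone: on random symmetric
affinities it overshoots within the first few iterations, raising the
objective by ~2% per step (the quartic reconstruction term invalidates the
step length that is safe for quadratic NMF). We therefore use the damped
form

    h ← h · ((1 − β) + β · ratio),    β = 1/2,

which for the unregularized problem is the provably monotone symmetric-NMF
rule, has the same fixed points for any `β ∈ (0, 1]`, and empirically never
increases the plain reconstruction objective. For the *regularized*
objective no monotonicity proof is available, and indeed a slow upward
drift of order 1e−8–1e−7 relative per step can appear long after the
convergence plateau. The fit loop therefore adds a backtracking safeguard:
if a step would increase the objective, β is halved (down to 1e−6) and the
step retried; if no damping decreases the objective the iterate is treated
as numerically stationary and the run stops as converged. The recorded
objective trace is non-increasing by construction, and the safeguard never
alters the update's fixed points.

**Denominator guard.** The ratio uses `max(denominator, 1e−12)` rather than
adding an epsilon: an additive epsilon biases the factor slightly below 1
at every fixed point, so `H` shrinks indefinitely and the objective drifts
upward post-convergence; `max` is exactly neutral whenever the denominator
is non-degenerate.

**Initialization.** NNDSVD adapted to the symmetric case: for each of the
leading `k` singular vectors of `A` (signs fixed so the largest-magnitude
coordinate is positive — LAPACK's sign choice is otherwise arbitrary), the
dominant non-negative section scaled by `√s_j` forms column `j` of `H₀`,
so `H₀H₀ᵀ` tracks the best rank-`k` approximation. Exact zeros are
perturbed to 1e−6 because multiplicative updates cannot leave exact zeros.
The start is deterministic, so identical inputs give bit-identical runs and
no restarts are needed. On well-separated data `H₀` is often already
near-optimal and the solver converges in a handful of iterations.

**Stopping.** Relative objective change `< 1e−6` (default) or 500
iterations, whichever first; the safeguard can also stop a run at a
numerically stationary point. The iteration cap and tolerance are exposed
in `FitConfig` / the CLI.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d` | 7 | neighbour whose distance sets the kernel bandwidth `σ_i` |
| `p` | 12 | neighbours kept by kNN sparsification of the global graph |
| `K` | 15 | Vicus local neighbourhood size |
| diffusion `α` | 0.9 | label-diffusion restart weight, in (0, 1) |
| reg. `α` | 0.01 | weight of both penalty terms; sweep grid {0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 10} |
| `k` | — | factorization rank = number of clusters (user-supplied) |
| `tol`, `max_iter` | 1e−6, 500 | stopping rule |
| `β` (damping) | 0.5 | multiplicative step damping; halved transiently by the safeguard |

`d` and `K` are clipped to `n − 1` on small inputs; bandwidths are floored
at 1e−12 so duplicated samples cannot divide by zero (`w = exp(0) = 1` for
coincident points, the correct limit).

## Degenerate inputs and tie-breaks

* Neighbour ranking everywhere: descending similarity, ties to the lower
  sample index (determinism across platforms).
* A zero row in a local subnetwork (sample disconnected from its
  neighbourhood) becomes a uniform transition row, the standard dangling-
  node convention in label diffusion.
* A centre that retains all diffusion mass (`β_i[K+1] → 1`) would make the
  reconstruction weights 0/0; the builder falls back to uniform weights
  with a warning. Unreachable through the public construction (the
  dangling-row rule and the zero diagonal prevent absorbing centres) but
  guarded anyway.
* An isolated node in the *sparsified* graph makes `D^{−1/2}` undefined;
  normalization raises an error naming the sample rather than silently
  regularizing, since an isolated sample usually signals an input problem
  (duplicate ids, a zero row, `p` far too small).
* All-zero rows of the fitted `H` are assigned to cluster 0 with a warning;
  all-zero columns are logged as a degenerate fit (fewer effective clusters
  than requested).

## Synthetic data

Three seeded generators stand in for real datasets so the package tests
end-to-end without downloads; all are pure functions of `(params, seed)`
with a documented draw order on one `numpy` PCG64 stream.

* **Gaussian blobs** — `k` isotropic clusters, centres rescaled so their
  minimum pairwise distance equals `separation` (default 10 with unit
  noise, i.e. clearly separated); shifted/clipped non-negative. Emulates
  log-scale expression-like data with cluster structure; the easiest
  regime, used for exact-recovery checks.
* **Compositional profiles** — per-cluster taxon probabilities drawn from
  a Dirichlet whose concentration is boosted (×20) on a cluster-specific
  block of taxa (concentration 0.5: sparse, strongly distinct signatures),
  then per-sample multinomial counts at the given depth, optionally
  row-normalized. Emulates species-level relative-abundance tables with
  body-site-like signatures. It does **not** model zero-inflation,
  phylogenetic correlation between taxa, sequencing batch effects, or
  overlapping community gradients — passing tests on this generator shows
  the pipeline recovers well-separated compositional structure, not that
  it resolves the subtler structure of real microbiome surveys.
* **Concentric rings** — two noisy circles (radii 1 and 3, noise 0.1),
  linearly inseparable by centroids but trivially separable on a
  neighbourhood graph; used to demonstrate why the pipeline clusters a
  graph rather than raw coordinates.

Study conditions used by the test suite and the acceptance script: 3
clusters × 30 samples for blobs (dim 10) and compositional data (100
taxa), 10 generator seeds per condition; solver sizes (n ≤ 30 graphs for
operator-level checks, 100 random instances for objective-behaviour
checks) are chosen so the whole suite runs in well under a minute-scale
budget on one CPU while still exercising every code path.

## Evaluation metrics

Accuracy: maximum fraction of agreeing samples over one-to-one mappings of
predicted to true cluster names, solved as linear assignment on the
contingency table (padded square when cluster counts differ). NMI:
`MI / sqrt(H_true · H_pred)` from the contingency table with natural logs;
arithmetic-mean and max normalizations are available for comparability
with other software. Degenerate conventions: two single-cluster partitions
are identical (NMI 1); if exactly one side has zero entropy, NMI is 0.
Both metrics are invariant to relabeling of either partition.

## Known limitations

* Dense `O(n²)`–`O(n³)` linear algebra throughout; intended for hundreds
  to a few thousand samples, not for n ≫ 10⁴.
* The regularized solver's monotonicity is enforced by safeguard, not
  proved; convergence is to a stationary point of the objective at best,
  and like all NMF-family methods the problem is non-convex — the
  deterministic NNDSVD start trades global-optimum guarantees for
  reproducibility.
* Rank `k` must be supplied; the package does not estimate the number of
  clusters.
* Distances are Euclidean on the rows as given. Compositional data are
  clustered on relative abundances directly; CLR or other transforms, if
  wanted, are the caller's preprocessing.
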