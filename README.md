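# lvsnmf

Graph-regularized symmetric non-negative matrix factorization for clustering
biological samples — microbiome relative-abundance profiles, expression
matrices, or any non-negative samples × features table.

## The method

Clustering starts from a sample–sample similarity graph rather than the raw
features. Given points `x_1 … x_n`, an adaptive Gaussian kernel

```
w_ij = exp( −‖x_i − x_j‖² / (σ_i σ_j) ),    σ_i = distance to the d-th neighbour
```

is sparsified to each sample's `p` nearest neighbours (an edge survives if
either endpoint keeps it) and normalized to `A = D^{−1/2} W D^{−1/2}`.
Symmetric NMF factorizes this affinity as `A ≈ H Hᵀ` with `H ≥ 0` of rank
`k` (the number of clusters); row `i` of `H` is a soft cluster indicator and
hard labels are its per-row argmax.

Two graph operators regularize the factorization:

* the **graph Laplacian** `L = D − P` of the sparsified graph, which
  penalizes `tr(Hᵀ L H)` and enforces *global* smoothness — neighbouring
  samples share factor values;
* the **Vicus local-spectral matrix** `V = (I − B)ᵀ (I − B)`, where row `i`
  of `B` holds the weights with which sample `i`'s `K` nearest neighbours
  reconstruct it under steady-state label diffusion
  `(1 − α)(I − α S_i)^{−1}` on its local subnetwork. `V` is symmetric, PSD
  and annihilates the constant vector, like `L`, but encodes *local*
  topology and is robust to outliers.

The full objective (the LVSNMF model) is

```
min_{H ≥ 0}  ‖A − H Hᵀ‖_F²  +  α [ tr(Hᵀ L H) + tr(Hᵀ V H) ]
```

solved by a damped multiplicative update with deterministic NNDSVD
initialization (no random restarts). With `V = V⁺ − V⁻` split by sign, the
update direction is

```
h ← h · (A H + α (P + V⁻) H) / (H Hᵀ H + α (D + V⁺) H)
```

applied with step damping β = 1/2 and a backtracking safeguard so the
objective trace is non-increasing (see `docs/methods.md`). Toggling the two
penalty terms yields four variants: `snmf`, `laplacian`, `vicus`, `lvsnmf`.

Defaults follow the reference settings: `d = 7`, `p = 12`, `K = 15`,
diffusion `α = 0.9`, regularization `α = 0.01`.

## Worked example

Generate a synthetic microbiome-style dataset (3 clusters × 30 samples,
100 taxa, Dirichlet-multinomial counts normalized to relative abundances)
and cluster it:

```
$ lvsnmf simulate --kind compositional --k 3 --n-per-cluster 30 \
      --n-taxa 100 --seed 11 --out demo
wrote demo_matrix.tsv (90 x 100) and demo_labels.tsv

$ lvsnmf cluster --input demo_matrix.tsv --k 3 \
      --labels demo_labels.tsv --out demo_run
fitted lvsnmf (k=3) in 1 iterations; converged=True
AC: 100.00%  NMI: 100.00%
```

`AC` is clustering accuracy after the optimal one-to-one matching of
predicted to true cluster labels (Hungarian method); `NMI` is normalized
mutual information (geometric-mean normalization). Both are printed as
percentages; 100% means the partition was recovered exactly. The run
directory contains `labels.tsv` (sample_id, cluster), the indicator matrix
`H.tsv`, the per-iteration `objective_trace.csv`, and `run_metadata.json`
with every parameter needed to re-execute the run. On this clean dataset the
NNDSVD start is already essentially optimal, hence the single iteration.

The same interface evaluates label files (`lvsnmf evaluate truth.tsv
pred.tsv`), exports the intermediate graph matrices (`lvsnmf graph`), and
sweeps the regularization weight or the Vicus neighbourhood size
(`lvsnmf sweep --input … --K-grid 10,15,20,25,30 --out report.csv`).

Library use mirrors the CLI:

```python
from lvsnmf import RunConfig, run_pipeline, make_blobs

ds = make_blobs(k=3, n_per_cluster=30, seed=0)
res = run_pipeline(RunConfig(k=3), ds)   # ds carries ground truth
print(res.accuracy, res.nmi)             # 1.0 1.0
```

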