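# tglrr

Subspace clustering and salient-gene selection for gene-expression
matrices by **t**runcated-nuclear-norm, **g**raph-Laplacian regularized
**l**ow-**r**ank **r**epresentation.

## The problem

Integrated tumor expression datasets pool samples from several cancer
types; the task is to recover the type of each sample without labels and
to identify the genes that drive the separation.  The working assumption
is the union-of-subspaces model: samples of each tumor class lie near
their own low-dimensional linear subspace of gene space, observations
carry dense noise, and a small fraction of entries are grossly corrupted.

## The model

Given an expression matrix **X** ∈ ℝ^{m×n} (m genes, n samples), the
package solves

```
min_{Z,G,P}  ||Z||_r + ||G||_* + (β/2)·Tr(Z L Zᵀ) + λ||P||₁
s.t.         X = X Z + G X + P
```

where

- **Z** ∈ ℝ^{n×n} is the sample representation (X itself is the
  self-expression dictionary); its low rank exposes subspace membership,
- **G** ∈ ℝ^{m×m} is the feature (gene-side) matrix; its rows rank genes,
- **P** ∈ ℝ^{m×n} collects sparse gross errors,
- ||Z||_r = Σ_{i>r} σ_i(Z) is the **truncated nuclear norm**: the r
  leading singular values are left unpenalized, giving a tighter rank
  surrogate than the nuclear norm,
- **L** is the Laplacian of a kNN graph over the samples, so Tr(Z L Zᵀ)
  keeps representations of neighboring samples similar.

The non-convex truncated norm is handled through its surrogate
||Z||_* − max_{AAᵀ=I, BBᵀ=I} Tr(A Z Bᵀ), and the whole problem is solved
by linearized ADMM with adaptive penalty (LADMAP): each iteration
refreshes (A, B) from the SVD of the current Z, then takes proximal
steps in Z, G, F (an auxiliary copy of Z), and P, followed by penalty
and multiplier updates.  Clusters come from K-means on the spectral
embedding of the affinity (|Z*| + |Z*ᵀ|)/2, scored by best-map accuracy
(ACC), max-normalized mutual information (NMI) and the pairwise
F-measure; genes are ranked by the row norms of G*.

## Worked example

```python
from tglrr import (
    SyntheticSpec, TGLRRParams, make_subspace_data, fit_tglrr,
    cluster_samples, aggregate_runs, score_genes,
    singular_value_curve, suggest_r,
)

spec = SyntheticSpec(
    n_clusters=3, subspace_dim=4, samples_per_cluster=(60, 60, 60),
    ambient_dim=200, noise_sigma=0.05, corruption_frac=0.01, seed=0,
)
data = make_subspace_data(spec)

print(f"suggested truncation rank r = {suggest_r(singular_value_curve(data.X))}")
result = fit_tglrr(data.X, TGLRRParams(lam=0.1, beta=1.0, max_iter=500))
print(f"converged = {result.converged} after {result.n_iter} iterations")
print(f"final relative residual = {result.history[-1]['residual']:.2e}")

runs = cluster_samples(result.Z_star, n_clusters=3, n_runs=10, seed=1)
ev = aggregate_runs(runs, data.labels)
print(f"ACC  = {ev.acc_mean:.4f} +/- {ev.acc_var:.4f}")
print(f"NMI  = {ev.nmi_mean:.4f} +/- {ev.nmi_var:.4f}")
print(f"F    = {ev.f_mean:.4f} +/- {ev.f_var:.4f}")
```

prints

```
suggested truncation rank r = 12
converged = True after 142 iterations
final relative residual = 9.73e-07
ACC  = 1.0000 +/- 0.0000
NMI  = 1.0000 +/- 0.0000
F    = 1.0000 +/- 0.0000
```

The suggested r = 12 is the inflection of the singular-value curve and
matches the planted rank (3 subspaces × dimension 4).  The solver
satisfies both constraints to a relative residual below 1e-6, and the 10
seeded K-means restarts all recover the planted partition exactly
(means are the averages over restarts, the ± values their population
variance).

## Command line

The same pipeline is available as a CLI:

```
tglrr simulate --n-clusters 3 --out sim/
tglrr suggest-r sim/expression.tsv
tglrr fit sim/expression.tsv --lam 0.1 --beta 1.0 --out fit/
tglrr evaluate sim/true_labels.tsv fit/Z_star.tsv --out metrics.json
tglrr select-genes fit/G_star.tsv sim/expression.tsv --out ranking.tsv
tglrr grid-search sim/expression.tsv sim/true_labels.tsv --out grid.tsv
tglrr run config.yaml --out results/     # config-driven end-to-end run
```

All inputs and outputs are delimited text (genes × samples, first row
sample ids, first column gene ids).

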