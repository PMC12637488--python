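# scfpcde

Trajectory-based differential expression for single-cell RNA-seq via
functional principal component analysis.

## The problem

After trajectory inference assigns each cell a pseudotime, a central
question is which genes change expression along that trajectory
(temporally differentially expressed genes, TDEGs). Generalized-additive-
model tests fit each gene independently against pseudotime and are known
to lose type-I-error control under the heavy zero inflation of droplet
scRNA-seq data. `scfpcde` instead treats each gene's log expression as a
smooth function of pseudotime in L², learns a *shared*, data-driven basis
— the eigenfunctions of the cross-gene covariance operator — and tests
each gene by how far its trajectory projects away from the flat function.

## The model

Each gene's log-transformed, mean-centered expression is represented as

  Y_i(t_j) = Σ_{k=1..L} ξ_ik Φ_k(t_j) + ε_i(t_j),

where the Φ_k are the top eigenfunctions of the pseudotime covariance
operator, ∫ C(s,t) Φ_k(s) ds = λ_k Φ_k(t), estimated from roughness-
penalized B-spline smooths of all genes, and ξ_ik are the functional
principal component (FPC) scores. The test statistic is the squared score
norm

  D_i = Σ_k ξ_ik²,

the squared L² distance between gene i's rank-L projection and the zero
function. Under H0 (ξ_ik = 0 for all k) D_i is small; its null
distribution is built by permuting pseudotime labels across cells, and
the empirical p-value pools null statistics across genes:

  p_i = (1 / B·G) Σ_b Σ_g 1{ D_g^(b) ≥ D_i }.

Because zero inflation dilutes the covariance estimate, the eigenbasis is
refined in two stages: an initial FPCA over all genes ranks them by D,
the top 25% (trajectory-informative genes, TIGs) re-estimate the
covariance and eigenfunctions, and all genes are re-projected and tested
against the refined basis. Benjamini–Hochberg FDR control gives the final
TDEG calls.

A companion simulator generates ground-truth-labelled zero-inflated data:
TDEG mean curves μ_i(t) = exp(Σ_k λ_k ξ_ik φ_k(t)) built from three damped
oscillation patterns φ₁ = e^{−t/2}cos 2πt, φ₂ = e^{−t/2}sin 2πt,
φ₃ = e^{−2t} with weights (1, 0.5, 0.25); flat null genes; counts
W = W⁰·Z with W⁰ ~ NB(μ, θ=1) and dropout indicator Z ~ Bernoulli(0.25),
giving ~92% zeros. A benchmark harness scores any method's p-values
against the truth (type-I error, power, ROC-AUC).

## Worked example

```python
import numpy as np
from scfpcde import ScFPCDE, SimulationConfig, simulate_dataset

data = simulate_dataset(SimulationConfig(n_genes=1000, n_tdeg=120, seed=42))
model = ScFPCDE(data.counts, data.t, scale="counts")
results = model.fit(n_permutations=100, seed=0)
print(results.summary(top=5))
```

prints

```
scFPC-DE trajectory differential expression
============================================================
genes: 1000    cells: 500
basis: BSplineBasis(n_basis=10, order=4, penalty_order=2), lambda = 0.3162
components L = 2 (cumulative variance 98.3%)
eigenvalues: 0.00124, 0.0005923
permutations B = 100 (pooled null), seed = 0
TIGs: 250    TDEGs (q < 0.05): 39
------------------------------------------------------------
gene_id       D  p  q  is_tig  is_tdeg
 gene47 0.05051  0  0    True     True
 gene92 0.02324  0  0    True     True
 gene11 0.01687  0  0    True     True
 gene55 0.01403  0  0    True     True
 gene82 0.01268  0  0    True     True
```

The header reports the smoothing penalty chosen by generalized
cross-validation (λ = 0.316), the number of retained components under the
90%-variance rule (L = 2, 98.3% of trajectory variance), and the calls:
250 genes kept as TIGs for the second-stage basis, 39 genes called TDEGs
at FDR q < 0.05. In this run all 39 calls are true simulated TDEGs. The
top table ranks genes by the distance statistic D; pooled permutation
p-values of 0 mean the observed D exceeded every one of the B·G null
draws. `results.to_frame()` returns the full per-gene table,
`results.cell_embedding()` projects cells into FPC space with the
pseudotime derivative field, and `results.plot_eigenfunctions()` /
`plot_gene()` / `plot_score_space()` visualize the fit.

The same pipeline is scriptable from the shell:

```sh
scfpcde simulate --preset high-zi --seed 1 --out sim/
scfpcde test --expr sim/matrix.mtx --pseudotime sim/pseudotime.tsv \
    --permutations 100 --seed 1 --out results/
scfpcde benchmark --preset high-zi --replicates 10 --seed 1
scfpcde embed --expr sim/matrix.mtx --pseudotime sim/pseudotime.tsv \
    --seed 1 --out embed/
```

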