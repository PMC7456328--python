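# Methods

## Problem and model

Given a cell-line x drug matrix R of log IC50 values with missing
entries, the package predicts the missing responses by a low-rank
factorization R ~ P Q^T (P: n x k cell-line factors, Q: m x k drug
factors) constrained by side information: a cell-line similarity matrix
SimC and a drug similarity matrix SimD. The objective is

    L(P, Q) = 1/2 Σ_{(i,j) observed} (r_ij − p_i·q_j)²
            + μ/2 (Σ_i ‖p_i‖² + Σ_j ‖q_j‖²)
            + λ/2 (Σ_{i,j} ‖p_i − p_j‖² SimC(i,j)
                   + Σ_{i,j} ‖q_i − q_j‖² SimD(i,j)).

The reconstruction sum runs over observed entries only; the fully-imputed
pipeline is the special case of an all-true mask (`treat_mask_as_full`
restores that reading explicitly). Similarities are built per feature
kind — Pearson correlation for continuous profiles (gene expression,
copy number), Jaccard index for binary profiles (mutations, chemical
fingerprints, drug targets, KEGG-pathway membership) — and by default
pass through the symmetric normalized Laplacian
S_norm = D^{-1/2}(D − S)D^{-1/2}, D_ii = Σ_j S_ij, before entering the
penalty. Every D_ii must be strictly positive; zero or negative row
sums (possible for predominantly negative correlations) are hard errors
rather than silent complex arithmetic.

## Optimization

Each row of P (and of Q) has a quadratic subproblem, so a single Newton
step lands on its exact minimizer:

    p_i ← [Σ_{j obs} r_ij q_j + λ Σ_{j≠i}(SimC(i,j)+SimC(j,i)) p_j] H_i^{-1},
    H_i = Σ_{j obs} q_j^T q_j + (μ + λ Σ_{j≠i}(SimC(i,j)+SimC(j,i))) I.

Sweeps over P then Q repeat until the Frobenius norm of the change in
the predicted matrix P Q^T drops below ε (default 0.01) or `max_iter`
(default 200) is reached. Self-pairs are excluded from the λ sums (their
derivative contribution is identically zero). An `as_printed` update
variant that keeps the row's own previous vector in the numerator is
available for comparison; the default `derived` variant is the exact
zero-gradient solution and gives a monotone non-increasing loss whenever
the block Hessians are positive definite.

Two runs are averaged: the forward fit of R, then a fit of R^T with the
similarity roles swapped, warm-started from the forward run's final
factors; the prediction is the elementwise mean of the two
reconstructions and is defined for all pairs, observed or not.

### Indefinite subproblems and the safeguard

The normalized Laplacian has non-positive off-diagonal entries, so the
λ "similarity" weights sum to roughly −2 per row and the manifold term
is a *negative* quadratic: it rewards spreading similar entities apart
and cancels against μ. When λ·2 approaches μ and the observed factor
Gram is near rank-deficient (low-rank data, k larger than the true
rank), row Hessians go indefinite and the objective can be unbounded
below. The solver handles this in two layers:

* a modified-Newton safeguard minimizes each row subproblem exactly on
  its positive-curvature eigendirections and freezes the row's current
  component along directions whose curvature falls below a scaled floor
  (1e-8·(1+|tr H|/k)); every row update is therefore non-increasing and
  bounded, and well-posed rows take the plain Cholesky solve;
* a genuinely unbounded configuration still descends without limit
  through well-posed steps; `fit` detects non-finite factors or loss and
  raises, and `grid_search(skip_failures=True)` records such grid points
  with fitness −inf so the tuning protocol simply avoids them.

Initialization draws factor entries uniformly from [0, 1). The O(1)
scale is deliberate: it keeps the initial Grams well conditioned (min
eigenvalue ~ m/12), where a k-dependent shrink would leave the first
sweep indefinite in exactly the marginal regimes described above.

## Hyperparameters

| parameter | meaning | default |
|---|---|---|
| k_percent | latent dimension as % of min(n, m) | 70 |
| μ | ridge coefficient on the factors | 8 |
| λ | similarity-conservation coefficient | 4 |
| ε | convergence tolerance on ‖ΔPQ^T‖_F | 0.01 |
| max_iter | iteration cap | 200 |
| n_neighbors | imputation neighbour count | 10 |
| n_folds / n_repeats | cross-validation layout | 5 / 30 |
| θ | redundancy-removal strictness | 0.20 |
| pathway coverage | max fraction of absent genes | 0.10 |

Defaults follow the reference protocol for real pharmacogenomic panels.
Note that the (μ=8, λ=4) pair sits exactly on the μ ≈ 2λ cancellation
boundary; on strongly low-rank data it can be ill-posed (see above), and
the intended usage is to re-tune by grid search per dataset — the
tooling for that (`grid_search`, `adrml tune`) maximizes the scalar
fitness = R² + PCC − RMSE under k-fold cross-validation on cell-drug
pairs, metrics averaged per fold then over folds and repeats, with
repeat seeds derived as master seed + repeat index. On the synthetic
benchmark the coarse grid (k' ∈ {50, 70}, μ ∈ {1, 8}, λ ∈ {1/8, 1, 4})
selects k'=50, μ=1, λ=1/8.

## Imputation

Features missing in strictly more than half the cell lines are dropped,
then cell lines missing strictly more than half the surviving features.
Remaining holes are filled from each cell line's `n_neighbors` nearest
neighbours in gene-expression space (squared Euclidean distance;
expression is assumed complete, so the neighbour graph always exists).
Continuous values take a weighted neighbour mean with weights
α_i = D(c,c_i)/Σ_j D(c,c_j) — proportional to distance, so *farther*
neighbours weigh more. That is the printed rule and is the default;
because it is counter-intuitive, `neighbor_weighting` also offers
`inverse_distance` and `uniform`. Neighbours missing the target column
are skipped with the weights renormalized; all-zero distances fall back
to uniform weights; ties in neighbour selection break by input label
order. Binary (mutation) entries take a strict majority vote of the
usable neighbours, ties giving 0.

## Downstream analyses

*Redundancy removal.* Within each tissue, the third quartile Q3(t) of the
off-diagonal pairwise similarities is computed (linear interpolation
between order statistics). A cell is excluded iff strictly more than
θ·n_t of the *other* cells in its tissue exceed Q3(t) in similarity,
with n_t the full tissue size; all removals are decided simultaneously
from the original composition, and singleton tissues are always kept.

*Pathway activity.* AS(c, p) = Σ_{g∈p present} ln(EXPR(c,g) / median_c
EXPR(·,g)); natural log (the base only rescales scores and cannot change
correlation signs). Pathways with more than 10% of genes absent from
the expression table are dropped; absent genes of retained pathways are
skipped. Drug-pathway association is the Pearson correlation of a
drug's predicted response vector with a pathway's activity vector over
the common cells; zero-variance columns yield NaN with a warning.

*Sensitivity calling.* Per drug, cells without an observed response are
ranked by predicted log IC50 (ties by cell label) and split into four
near-equal groups, earlier groups absorbing remainders; the lowest group
is called sensitive, the highest resistant. Drugs with fewer than four
unmeasured cells produce empty calls with a warning.

## Synthetic data

The generator emulates the shape of a pharmacogenomic benchmark: a rank-k
response P Q^T + N(0, σ²) with an exact fraction of entries masked
uniformly at random; expression as the exponential of a per-gene
baseline plus a linear image of the cell factors (strictly positive, and
the shared baseline makes cell-cell correlations predominantly positive
as in real panels — necessary for the Laplacian's positive-degree
requirement); copy number as a baseline-plus-latent-image real table;
mutation and drug feature tables as thresholded latent images with
guaranteed per-row support (expected densities 0.2 and 0.1); tissue
labels doubling as the latent cluster structure so redundancy removal
has signal; and random gene sets over the expression genes. Default
study conditions for the recovery benchmark: n=100 cells, m=20 drugs,
200 genes, rank 5, σ=0.1, 20% missing, 4 tissues.

What the generator does **not** emulate: real IC50 scales and marginals,
dose-response measurement error structure, linkage between mutation and
expression, or realistic fingerprint sparsity patterns. Passing recovery
tests therefore demonstrate correctness of the estimator under its own
modelling assumptions, not predictive performance on GDSC/CCLE-class
data.

## Numerical choices and limitations

* Metrics: RMSE, R² (1 − SSE/SST, can be negative), Pearson correlation;
  per-fold then averaged; fitness from the aggregate means.
* Cross-validation folds partition the observed cell-drug pairs (sizes
  differ by at most one, seeded shuffle); held-out entries are removed
  from the training mask, not zero-filled.
* The KNN (k=1) baseline featurizes a pair as the concatenation of its
  cell's similarity row and its drug's similarity column, with
  scikit-learn's nearest-neighbour regressor underneath.
* Problem sizes in the test-suite and acceptance protocol are scaled to
  the synthetic benchmark above (the full 9x7x7 grid and 30-repeat CV of
  a real study are supported but not exercised by default); convergence
  on these instances takes ~30-60 sweeps at ε=0.01.
* No cold-start extrapolation: cells/drugs absent from the similarity
  matrices cannot be predicted. No nonnegativity constraints, no
  stochastic solvers.
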