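# adrml

Anticancer drug response prediction by similarity-constrained manifold
learning.

Precision oncology needs estimates of how a cell line (and ultimately a
patient) will respond to a drug it has never been tested against. Given
a partially observed cell-line x drug matrix of log IC50 values, this
package predicts the missing responses by factorizing the response
matrix into low-rank latent factors, R ≈ P Qᵀ, under a manifold
constraint that ties the latent geometry to molecular similarity:

    L = ½ Σ_{(i,j) obs} (r_ij − p_i·q_jᵀ)²
      + μ/2 (Σ‖p_i‖² + Σ‖q_j‖²)
      + λ/2 (Σ_{i,j}‖p_i−p_j‖² SimC(i,j) + Σ_{i,j}‖q_i−q_j‖² SimD(i,j))

SimC is a cell-line similarity (Pearson correlation of expression or
copy-number profiles, Jaccard index of mutation profiles) and SimD a
drug similarity (Jaccard index of chemical fingerprints, target
proteins, or KEGG-pathway membership), both normalized through the
symmetric normalized Laplacian by default. The factors are found by
alternating exact Newton row updates, a second run on the transposed
problem is averaged in, and unknown responses are read off P Qᵀ.

Around that core the package provides the full study pipeline:
expression-distance weighted KNN imputation of missing IC50/CNV/mutation
values, similarity construction and normalization, repeated k-fold
cross-validation on cell-drug pairs with RMSE / R² / Pearson metrics and
the fitness score R² + PCC − RMSE, grid-search hyperparameter tuning, a
KNN (k=1) baseline, tissue-wise redundancy removal for benchmark
purification, pathway activity scoring with drug-pathway association,
quartile-based sensitive/resistant calling, and a seeded synthetic-data
generator so every stage is testable without external downloads.

Intended users: computational biologists working with pharmacogenomic
panels (GDSC/CCLE-style data) and methodologists studying
similarity-regularized matrix completion.

## Worked example

All stages are available both as a library and through the `adrml`
command. A complete run on generated data:

```sh
adrml simulate --out demo --n 60 --m 12 --k 3 --seed 42
adrml similarity --features demo/expr.tsv --kind expr --out demo/simC.tsv
adrml similarity --features demo/chem.tsv --kind chem --out demo/simD.tsv
adrml cv --response demo/response.tsv --simc demo/simC.tsv --simd demo/simD.tsv \
         --out demo/cv --n-folds 5 --n-repeats 1 \
         --k-percent 50 --mu 1 --lam 0.125 --seed 42
adrml fit --response demo/response.tsv --simc demo/simC.tsv --simd demo/simD.tsv \
          --out demo/fit --k-percent 50 --mu 1 --lam 0.125 --seed 42
```

which prints

```
wrote synthetic dataset to demo
RMSE 0.4961  R2 0.8966  PCC 0.9676  fitness 1.3680
converged=True after 34 iterations, loss 58.0984
```

The `cv` line is the 5-fold cross-validation on held-out cell-drug
pairs: predictions correlate with the held-out responses at r = 0.97,
explain 90% of their variance, and miss by 0.50 on the log IC50 scale
(the simulated noise floor is σ = 0.1, but one fifth of the training
entries are masked); fitness is the scalar used for model selection.
The `fit` line reports the alternating-Newton solve on all observed
entries: 34 sweeps to a prediction change below ε = 0.01. `demo/fit/`
then holds the latent factor matrices, and `adrml predict` writes the
full predicted response matrix for downstream `pathway` and `call`
analyses.

The same pipeline in Python:

```python
import adrml

data = adrml.simulate(adrml.SyntheticParams(n=60, m=12, k=3, seed=42))
simC = adrml.build_similarity(data.expr)
simD = adrml.build_similarity(data.chem)
hyper = adrml.HyperParams(k_percent=50, mu=1.0, lam=0.125, seed=42)
report = adrml.cross_validate(data.response, simC, simD, hyper,
                              n_folds=5, n_repeats=1, seed=42)
print(report.aggregate_pcc)   # 0.9676...
```

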