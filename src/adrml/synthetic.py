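"""Seeded generator of pipeline-shaped datasets with known ground truth.

Emulates the structure of a pharmacogenomic benchmark at small scale: a
low-rank cell x drug log IC50 matrix with Gaussian noise and missing
entries, molecular feature tables (expression, copy number, mutation)
that are noisy images of the cell-line latent factors, binary drug
feature tables (fingerprint, targets, pathway membership) derived from
the drug latent factors, tissue labels that double as the latent
correlation structure, and gene sets over the expression genes.  Every
table is reproducible bit-for-bit from the seed, and the generating
factors are retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from adrml.io import (
    FeatureTable,
    GeneSetCollection,
    ResponseMatrix,
    TissueAnnotation,
)


@dataclass
class SyntheticParams:
    """Shape and noise parameters of a synthetic dataset.

    n, m : numbers of cell lines and drugs.
    n_genes : genes in the expression/CNV/mutation tables.
    k : true latent rank of the response matrix.
    sigma : standard deviation of the Gaussian noise on responses.
    missing_fraction : exact fraction of response entries masked out.
    n_tissues : number of tissue clusters (cells in one cluster have
        correlated latent vectors).
    n_drug_features : width of each binary drug feature table.
    n_pathways : number of generated gene sets.
    seed : master seed.
    """

    n: int = 100
    m: int = 20
    n_genes: int = 200
    k: int = 5
    sigma: float = 0.1
    missing_fraction: float = 0.2
    n_tissues: int = 4
    n_drug_features: int = 32
    n_pathways: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 2:
            raise ValueError("need at least 2 cell lines and 2 drugs")
        if not 1 <= self.k <= min(self.n, self.m):
            raise ValueError(f"k must lie in [1, {min(self.n, self.m)}], got {self.k}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.n_tissues < 1 or self.n_tissues > self.n:
            raise ValueError("n_tissues must lie in [1, n]")


@dataclass
class SyntheticDataset:
    """Generated tables plus the factors that produced them."""

    truth_P: np.ndarray
    truth_Q: np.ndarray
    response: ResponseMatrix
    expr: FeatureTable
    cnv: FeatureTable
    mut: FeatureTable
    chem: FeatureTable
    trgt: FeatureTable
    kegg: FeatureTable
    tissues: TissueAnnotation
    gene_sets: GeneSetCollection
    params: SyntheticParams


def _binary_from_latent(
    rng: np.random.Generator,
    latent: np.ndarray,
    n_features: int,
    density: float,
) -> np.ndarray:
    """Threshold a noisy linear image of the latent rows into 0/1.

    The threshold is the (1 - density) quantile of the scores, so the
    expected fill rate is ``density``; all-zero rows get their top-scoring
    feature switched on so Jaccard similarity stays defined.
    """
    k = latent.shape[1]
    proj = rng.standard_normal((k, n_features))
    scores = latent @ proj / np.sqrt(k) + 0.3 * rng.standard_normal(
        (latent.shape[0], n_features)
    )
    cutoff = np.quantile(scores, 1.0 - density)
    binary = (scores > cutoff).astype(float)
    for i in np.nonzero(binary.sum(axis=1) == 0)[0]:
        binary[i, int(np.argmax(scores[i]))] = 1.0
    return binary


def simulate(params: SyntheticParams | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset from the given parameters."""
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed)
    n, m, k = params.n, params.m, params.k

    cell_ids = [f"C{i:04d}" for i in range(n)]
    drug_ids = [f"D{j:03d}" for j in range(m)]
    gene_ids = [f"G{g:04d}" for g in range(params.n_genes)]

    # tissue clusters share a latent center -> within-tissue correlation
    tissue_idx = np.array([i % params.n_tissues for i in range(n)])
    centers = rng.standard_normal((params.n_tissues, k))
    share = np.sqrt(0.5)
    truth_P = share * centers[tissue_idx] + share * rng.standard_normal((n, k))
    truth_Q = rng.standard_normal((m, k))

    clean = truth_P @ truth_Q.T
    noisy = clean + params.sigma * rng.standard_normal((n, m))
    n_missing = round(params.missing_fraction * n * m)
    flat = rng.permutation(n * m)[:n_missing]
    observed = np.ones(n * m, dtype=bool)
    observed[flat] = False
    observed = observed.reshape(n, m)
    values = np.where(observed, noisy, np.nan)
    response = ResponseMatrix(cell_ids, drug_ids, values, observed)

    # expression: exponentiated linear image of P (strictly positive); a
    # shared per-gene baseline mimics the common expression-level profile
    # that makes real cell-cell correlations strongly positive
    gene_baseline = 0.8 * rng.standard_normal(params.n_genes)
    proj_e = rng.standard_normal((k, params.n_genes))
    log_expr = (
        gene_baseline
        + 0.7 * truth_P @ proj_e / np.sqrt(k)
        + 0.2 * rng.standard_normal((n, params.n_genes))
    )
    expr = FeatureTable(cell_ids, list(gene_ids), np.exp(0.5 * log_expr), "EXPR")

    # copy number: shared per-gene deviation plus a latent image, so the
    # pairwise correlations stay predominantly positive as in real panels
    cnv_baseline = 0.8 * rng.standard_normal(params.n_genes)
    proj_c = rng.standard_normal((k, params.n_genes))
    cnv_values = (
        cnv_baseline
        + 0.7 * truth_P @ proj_c / np.sqrt(k)
        + 0.3 * rng.standard_normal((n, params.n_genes))
    )
    cnv = FeatureTable(cell_ids, list(gene_ids), cnv_values, "CNV")

    mut_values = _binary_from_latent(rng, truth_P, params.n_genes, density=0.2)
    mut = FeatureTable(cell_ids, list(gene_ids), mut_values, "MUT")

    feature_ids = lambda prefix: [f"{prefix}{j:03d}" for j in range(params.n_drug_features)]
    chem = FeatureTable(
        drug_ids,
        feature_ids("F"),
        _binary_from_latent(rng, truth_Q, params.n_drug_features, density=0.1),
        "CHEM",
    )
    trgt = FeatureTable(
        drug_ids,
        feature_ids("P"),
        _binary_from_latent(rng, truth_Q, params.n_drug_features, density=0.1),
        "TRGT",
    )
    kegg = FeatureTable(
        drug_ids,
        feature_ids("K"),
        _binary_from_latent(rng, truth_Q, params.n_drug_features, density=0.1),
        "KEGG",
    )

    tissues = TissueAnnotation(
        {cell: f"T{tissue_idx[i]}" for i, cell in enumerate(cell_ids)}
    )

    sets: dict[str, list[str]] = {}
    for p in range(params.n_pathways):
        size = int(rng.integers(5, 16))
        members = rng.choice(params.n_genes, size=min(size, params.n_genes), replace=False)
        sets[f"PW{p:02d}"] = [gene_ids[g] for g in sorted(members)]
    gene_sets = GeneSetCollection(sets)

    return SyntheticDataset(
        truth_P=truth_P,
        truth_Q=truth_Q,
        response=response,
        expr=expr,
        cnv=cnv,
        mut=mut,
        chem=chem,
        trgt=trgt,
        kegg=kegg,
        tissues=tissues,
        gene_sets=gene_sets,
        params=params,
    )


def inject_missing(table: FeatureTable, fraction: float, seed: int) -> FeatureTable:
    """Mask an exact fraction of entries uniformly at random.

    Expression tables are refused (the pipeline assumes complete
    expression so the imputation neighbour graph stays defined).  Masked
    entries are set to NaN.
    """
    if table.kind == "EXPR":
        raise ValueError("expression tables must stay fully observed")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    out = table.copy()
    if fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    size = out.values.size
    n_new = round(fraction * size)
    chosen = rng.permutation(size)[:n_new]
    mask = out.missing_mask.reshape(-1)
    mask[chosen] = True
    values = out.values.reshape(-1)
    values[chosen] = np.nan
    return FeatureTable(
        list(out.entity_ids),
        list(out.feature_ids),
        values.reshape(out.values.shape),
        out.kind,
        mask.reshape(out.values.shape),
    )
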