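"""Similarity matrices and their Laplacian normalization.

Continuous feature kinds (gene expression, copy number) are compared with
the Pearson correlation coefficient; binary kinds (mutation calls, chemical
fingerprints, target proteins, KEGG-pathway membership) with the Jaccard
index.  The resulting matrices can be normalized with the symmetric
normalized Laplacian D^{-1/2} (D - S) D^{-1/2}, which is the form the
factorization consumes by default.
"""

from __future__ import annotations

import numpy as np

from adrml.io import BINARY_KINDS, CONTINUOUS_KINDS, FeatureTable, SimilarityMatrix


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length real vectors.

    Raises on vectors shorter than 2 or with zero variance (the
    denominator would vanish).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must share one shape, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("correlation needs at least 2 elements")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(xc @ xc) * np.sqrt(yc @ yc)
    if denom == 0.0:
        raise ValueError("zero-variance vector in correlation")
    return float((xc @ yc) / denom)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard index |x & y| / |x | y| of two binary vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must share one shape, got {x.shape} vs {y.shape}")
    if not (np.all(np.isin(x, (0.0, 1.0))) and np.all(np.isin(y, (0.0, 1.0)))):
        raise ValueError("jaccard requires binary vectors")
    inter = float(np.sum(x * y))
    union = float(np.sum(x) + np.sum(y)) - inter
    if union == 0.0:
        raise ValueError("jaccard undefined for two all-zero vectors")
    return inter / union


def build_similarity(features: FeatureTable) -> SimilarityMatrix:
    """Pairwise similarity of all entities in a fully observed feature table.

    Kind EXPR/CNV -> Pearson correlation; MUT/CHEM/TRGT/KEGG -> Jaccard.
    Degenerate rows (zero variance for the correlation kinds, all-zero for
    the Jaccard kinds) are an error naming the entity.
    """
    if features.missing_mask.any():
        raise ValueError("similarity requires a fully observed feature table")
    X = features.values
    n = features.n_entities
    if n < 2:
        raise ValueError("similarity needs at least 2 entities")
    if features.kind in CONTINUOUS_KINDS:
        sd = X.std(axis=1)
        bad = np.nonzero(sd == 0.0)[0]
        if bad.size:
            raise ValueError(
                f"entity {features.entity_ids[bad[0]]!r} has a constant "
                "feature vector; correlation undefined"
            )
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.sum(Xc * Xc, axis=1))
        S = (Xc @ Xc.T) / np.outer(norms, norms)
        np.clip(S, -1.0, 1.0, out=S)
    elif features.kind in BINARY_KINDS:
        support = X.sum(axis=1)
        bad = np.nonzero(support == 0.0)[0]
        if bad.size:
            raise ValueError(
                f"entity {features.entity_ids[bad[0]]!r} has an all-zero "
                "feature vector; Jaccard undefined"
            )
        inter = X @ X.T
        union = support[:, None] + support[None, :] - inter
        S = inter / union
    else:  # pragma: no cover - FeatureTable validates kinds
        raise ValueError(f"unknown feature kind {features.kind!r}")
    S = (S + S.T) / 2.0  # enforce exact symmetry against float round-off
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(features.entity_ids), S, features.kind, normalized=False)


def normalize_similarity(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric normalized Laplacian of a raw similarity matrix.

    With D = diag(row sums of S) and L = D - S, returns
    D^{-1/2} L D^{-1/2}.  Every row sum must be strictly positive: a zero
    row sum leaves the scaling undefined and a negative one (possible for
    predominantly negative correlations) would require complex square
    roots, so both are hard errors.
    """
    if sim.normalized:
        raise ValueError("similarity matrix is already normalized")
    S = sim.values
    d = S.sum(axis=1)
    zero = np.nonzero(d == 0.0)[0]
    if zero.size:
        raise ValueError(
            f"row sum of entity {sim.entity_ids[zero[0]]!r} is zero; "
            "Laplacian scaling undefined"
        )
    neg = np.nonzero(d < 0.0)[0]
    if neg.size:
        raise ValueError(
            f"row sum of entity {sim.entity_ids[neg[0]]!r} is negative; "
            "Laplacian scaling undefined (square root of a negative degree)"
        )
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.diag(d) - S
    out = L * np.outer(inv_sqrt, inv_sqrt)
    out = (out + out.T) / 2.0
    return SimilarityMatrix(list(sim.entity_ids), out, sim.kind, normalized=True)
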