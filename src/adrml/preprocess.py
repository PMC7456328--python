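"""Missing-data filtering and expression-distance weighted KNN imputation.

Cell-line feature tables (IC50 responses, copy-number values, mutation
calls) arrive with holes.  Features missing in a majority of cell lines
are dropped, then cell lines missing a majority of the surviving features
are dropped, and the remaining holes are filled from each cell line's
nearest neighbours in gene-expression space.  Expression itself is
assumed complete, so the neighbour graph is always well defined.

The neighbour weights are proportional to the squared-Euclidean
expression distance, renormalized over the neighbours actually usable
for a given column: alpha_i = D(c, c_i) / sum_j D(c, c_j).  Note that
this weighs *farther* neighbours more; an inverse-distance and a uniform
weighting are available via ``ImputationConfig.neighbor_weighting`` for
users who prefer the conventional scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from adrml.io import FeatureTable, ResponseMatrix

WEIGHTINGS = ("as_printed", "inverse_distance", "uniform")


@dataclass
class ImputationConfig:
    """Settings for filtering and KNN imputation.

    n_neighbors : size of the nearest-neighbour set (clipped to n-1 on
        small datasets).  Default 10.
    feature_drop_fraction : drop a feature if it is missing in strictly
        more than this fraction of entities.  Default 0.5.
    sample_drop_fraction : after feature dropping, drop an entity missing
        strictly more than this fraction of the surviving features.
        Default 0.5.
    neighbor_weighting : 'as_printed' (weights proportional to squared
        expression distance), 'inverse_distance', or 'uniform'.
    """

    n_neighbors: int = 10
    feature_drop_fraction: float = 0.5
    sample_drop_fraction: float = 0.5
    neighbor_weighting: str = "as_printed"

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        for name in ("feature_drop_fraction", "sample_drop_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.neighbor_weighting not in WEIGHTINGS:
            raise ValueError(
                f"neighbor_weighting must be one of {WEIGHTINGS}, got "
                f"{self.neighbor_weighting!r}"
            )


def filter_missing(table: FeatureTable, config: ImputationConfig | None = None) -> FeatureTable:
    """Drop heavily missing features, then heavily missing entities.

    A feature is dropped when missing in strictly more than
    ``feature_drop_fraction`` of entities; afterwards an entity is
    dropped when missing strictly more than ``sample_drop_fraction`` of
    the surviving features.  Label order is preserved.
    """
    config = config or ImputationConfig()
    n, p = table.values.shape
    feat_missing = table.missing_mask.mean(axis=0)
    keep_feat = feat_missing <= config.feature_drop_fraction
    if not keep_feat.any():
        raise ValueError("all features dropped by the missingness filter")
    sub_mask = table.missing_mask[:, keep_feat]
    entity_missing = sub_mask.mean(axis=1)
    keep_ent = entity_missing <= config.sample_drop_fraction
    if not keep_ent.any():
        raise ValueError("all entities dropped by the missingness filter")
    return FeatureTable(
        [e for e, k in zip(table.entity_ids, keep_ent) if k],
        [f for f, k in zip(table.feature_ids, keep_feat) if k],
        table.values[np.ix_(keep_ent, keep_feat)],
        table.kind,
        table.missing_mask[np.ix_(keep_ent, keep_feat)],
    )


def expression_distance(expr: FeatureTable, cell_a: str, cell_b: str) -> float:
    """Squared Euclidean distance between two expression profiles."""
    if expr.missing_mask.any():
        raise ValueError("expression table must be fully observed")
    diff = expr.row(cell_a) - expr.row(cell_b)
    return float(diff @ diff)


def _distance_matrix(expr: FeatureTable) -> np.ndarray:
    """All pairwise squared Euclidean distances between expression rows."""
    X = expr.values
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _neighbor_sets(
    expr: FeatureTable, cells: list[str], config: ImputationConfig
) -> tuple[list[list[int]], np.ndarray]:
    """Per-cell nearest-neighbour index lists (into ``cells``) and distances.

    One neighbour set per cell, computed once from expression and reused
    across every imputed column.  Ties in distance are broken by input
    label order (stable argsort).
    """
    pos = {lab: i for i, lab in enumerate(expr.entity_ids)}
    try:
        order = [pos[c] for c in cells]
    except KeyError as exc:
        raise KeyError(f"cell {exc.args[0]!r} absent from expression table") from None
    D_full = _distance_matrix(expr)
    D = D_full[np.ix_(order, order)]
    n = len(cells)
    if n < 2:
        raise ValueError("imputation needs at least 2 cell lines")
    k = min(config.n_neighbors, n - 1)
    neighbors: list[list[int]] = []
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf  # a cell is never its own neighbour
        idx = np.argsort(d, kind="stable")[:k]
        neighbors.append(list(idx))
    return neighbors, D


def _weights(distances: np.ndarray, scheme: str) -> np.ndarray:
    """Convex weights over a usable neighbour subset (sum to 1)."""
    if len(distances) == 1:
        return np.ones(1)
    if scheme == "uniform":
        return np.full(len(distances), 1.0 / len(distances))
    if scheme == "inverse_distance":
        if np.any(distances == 0.0):
            # zero-distance neighbours dominate; split evenly among them
            zero = distances == 0.0
            w = np.where(zero, 1.0, 0.0)
            return w / w.sum()
        inv = 1.0 / distances
        return inv / inv.sum()
    # as_printed: alpha_i proportional to the distance itself
    total = distances.sum()
    if total == 0.0:
        return np.full(len(distances), 1.0 / len(distances))
    return distances / total


def impute_continuous(
    target: ResponseMatrix | FeatureTable,
    expr: FeatureTable,
    config: ImputationConfig | None = None,
):
    """Fill missing continuous entries from expression-nearest neighbours.

    Each missing entry (c, col) becomes the weighted mean of the same
    column over c's nearest neighbours whose own entry is observed;
    weights follow ``config.neighbor_weighting`` and are renormalized
    over the usable neighbours.  Observed entries are untouched and the
    output is fully observed.
    """
    config = config or ImputationConfig()
    if isinstance(target, ResponseMatrix):
        cells = target.cell_ids
        values = target.values.copy()
        missing = ~target.observed_mask
    else:
        cells = target.entity_ids
        values = target.values.copy()
        missing = target.missing_mask.copy()
    if not missing.any():
        return target.copy()
    neighbors, D = _neighbor_sets(expr, list(cells), config)
    observed = ~missing
    for i, j in zip(*np.nonzero(missing)):
        nn = [h for h in neighbors[i] if observed[h, j]]
        if not nn:
            col = (
                target.drug_ids[j]
                if isinstance(target, ResponseMatrix)
                else target.feature_ids[j]
            )
            raise ValueError(
                f"cannot impute ({cells[i]!r}, {col!r}): no neighbour has an "
                "observed value"
            )
        w = _weights(D[i, nn], config.neighbor_weighting)
        values[i, j] = float(w @ values[nn, j])
    if isinstance(target, ResponseMatrix):
        return ResponseMatrix(
            list(target.cell_ids),
            list(target.drug_ids),
            values,
            np.ones_like(missing, dtype=bool),
        )
    return FeatureTable(
        list(target.entity_ids),
        list(target.feature_ids),
        values,
        target.kind,
        np.zeros_like(missing, dtype=bool),
    )


def impute_binary(
    target: FeatureTable, expr: FeatureTable, config: ImputationConfig | None = None
) -> FeatureTable:
    """Fill missing mutation calls by strict majority vote of neighbours.

    A missing (cell, gene) entry becomes 1 iff mutated neighbours strictly
    outnumber wild-type neighbours among the usable nearest neighbours;
    ties give 0.
    """
    config = config or ImputationConfig()
    values = target.values.copy()
    missing = target.missing_mask.copy()
    if not missing.any():
        return target.copy()
    neighbors, _ = _neighbor_sets(expr, list(target.entity_ids), config)
    observed = ~missing
    for i, j in zip(*np.nonzero(missing)):
        nn = [h for h in neighbors[i] if observed[h, j]]
        if not nn:
            raise ValueError(
                f"cannot impute ({target.entity_ids[i]!r}, "
                f"{target.feature_ids[j]!r}): no neighbour has an observed value"
            )
        ones = float(values[nn, j].sum())
        zeros = len(nn) - ones
        values[i, j] = 1.0 if ones > zeros else 0.0
    return FeatureTable(
        list(target.entity_ids),
        list(target.feature_ids),
        values,
        target.kind,
        np.zeros_like(missing, dtype=bool),
    )
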