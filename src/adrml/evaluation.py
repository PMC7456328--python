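"""Cross-validation on cell-drug pairs, metrics, grid search, KNN baseline.

Evaluation treats every observed (cell line, drug) response as one
sample.  Samples are partitioned into near-equal folds; each fold is
masked out of the training data in turn, the factorization is re-fit,
and RMSE, R^2 and Pearson correlation are computed on the held-out
entries only.  Metrics are computed per fold and then averaged; a
scalar fitness = R^2 + PCC - RMSE summarizes a configuration for grid
search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from adrml.factorization import HyperParams, predict_dual
from adrml.io import ResponseMatrix, SimilarityMatrix
from adrml.similarity import pcc

logger = logging.getLogger(__name__)


def rmse(real_values: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error between paired vectors."""
    real_values = np.asarray(real_values, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if real_values.shape != predicted.shape or real_values.ndim != 1:
        raise ValueError(
            f"vectors must share one shape, got {real_values.shape} vs {predicted.shape}"
        )
    if real_values.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    diff = real_values - predicted
    return float(np.sqrt(np.mean(diff * diff)))


def r_squared(real_values: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST (can be negative)."""
    real_values = np.asarray(real_values, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if real_values.shape != predicted.shape or real_values.ndim != 1:
        raise ValueError(
            f"vectors must share one shape, got {real_values.shape} vs {predicted.shape}"
        )
    sst = float(np.sum((real_values - real_values.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined for constant real values")
    sse = float(np.sum((real_values - predicted) ** 2))
    return 1.0 - sse / sst


#: Pearson correlation between held-out truth and predictions.
pcc_metric = pcc


def fitness(r2: float, pcc_value: float, rmse_value: float) -> float:
    """Scalar model quality: R^2 + PCC - RMSE (higher is better)."""
    return r2 + pcc_value - rmse_value


@dataclass
class EvalReport:
    """Per-fold and aggregated cross-validation metrics."""

    per_fold: list[tuple[float, float, float]]  # (rmse, r2, pcc) per fold
    aggregate_rmse: float
    aggregate_r2: float
    aggregate_pcc: float
    fitness: float
    n_folds: int
    n_repeats: int
    seed: int
    per_drug_pcc: dict[str, float] = field(default_factory=dict)


@dataclass
class GridSpec:
    """Hyperparameter grid for tuning (defaults follow the reference grid)."""

    k_percents: list[float] = field(
        default_factory=lambda: [10, 20, 30, 40, 50, 60, 70, 80, 90]
    )
    mus: list[float] = field(default_factory=lambda: [2.0**e for e in range(-3, 4)])
    lams: list[float] = field(default_factory=lambda: [2.0**e for e in range(-3, 4)])

    def __post_init__(self) -> None:
        if not (self.k_percents and self.mus and self.lams):
            raise ValueError("grid lists must be non-empty")


def make_folds(n_pairs: int, n_folds: int, seed: int) -> np.ndarray:
    """Random near-equal fold assignment (one integer in [0, n_folds) per pair)."""
    if n_pairs < n_folds:
        raise ValueError(f"cannot split {n_pairs} pairs into {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignment = np.arange(n_pairs) % n_folds  # sizes differ by at most 1
    rng.shuffle(assignment)
    return assignment


def _fold_metrics(real: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    return (
        rmse(real, predicted),
        r_squared(real, predicted),
        pcc_metric(real, predicted),
    )


def cross_validate(
    R: ResponseMatrix,
    simC: SimilarityMatrix,
    simD: SimilarityMatrix,
    hyper: HyperParams | None = None,
    n_folds: int = 5,
    n_repeats: int = 30,
    seed: int = 0,
) -> EvalReport:
    """Repeated k-fold cross-validation over observed cell-drug pairs.

    Per repeat, the observed pairs are partitioned into ``n_folds`` folds
    from a repeat-specific seed (master seed + repeat index); each fold is
    removed from the training mask, the dual-run factorization is fit on
    the remainder, and the metrics are computed on the held-out pairs.
    Aggregates are means over all folds of all repeats; fitness is
    computed from the aggregates.
    """
    hyper = hyper or HyperParams()
    pairs = np.argwhere(R.observed_mask)
    if len(pairs) < n_folds:
        raise ValueError(f"only {len(pairs)} observed pairs for {n_folds} folds")
    per_fold: list[tuple[float, float, float]] = []
    pooled_real: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for repeat in range(n_repeats):
        assignment = make_folds(len(pairs), n_folds, seed + repeat)
        for fold in range(n_folds):
            held = pairs[assignment == fold]
            train = R.copy()
            train.observed_mask[held[:, 0], held[:, 1]] = False
            train.values[held[:, 0], held[:, 1]] = np.nan
            if not train.observed_mask.any(axis=1).all() or not train.observed_mask.any(axis=0).all():
                logger.warning(
                    "repeat %d fold %d empties a row or column of training "
                    "entries; prediction relies on the similarity coupling",
                    repeat,
                    fold,
                )
            result = predict_dual(train, simC, simD, hyper)
            real = R.values[held[:, 0], held[:, 1]]
            pred = result.combined[held[:, 0], held[:, 1]]
            per_fold.append(_fold_metrics(real, pred))
            pooled_real.append(real)
            pooled_pred.append(pred)
    agg = np.mean(np.array(per_fold), axis=0)
    agg_rmse, agg_r2, agg_pcc = (float(v) for v in agg)
    # per-drug correlations from the pooled held-out predictions of the
    # final repeat (each pair held out exactly once per repeat)
    last = slice(len(per_fold) - n_folds, len(per_fold))
    pred_full = np.full(R.values.shape, np.nan)
    for real, pred, fold in zip(pooled_real[last], pooled_pred[last], range(n_folds)):
        held = pairs[make_folds(len(pairs), n_folds, seed + n_repeats - 1) == fold]
        pred_full[held[:, 0], held[:, 1]] = pred
    per_drug = drugwise_pcc(R, pred_full)
    return EvalReport(
        per_fold=per_fold,
        aggregate_rmse=agg_rmse,
        aggregate_r2=agg_r2,
        aggregate_pcc=agg_pcc,
        fitness=fitness(agg_r2, agg_pcc, agg_rmse),
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
        per_drug_pcc=per_drug,
    )


def grid_search(
    R: ResponseMatrix,
    simC: SimilarityMatrix,
    simD: SimilarityMatrix,
    grid: GridSpec | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_repeats: int = 1,
    base: HyperParams | None = None,
    skip_failures: bool = False,
) -> tuple[HyperParams, list[dict]]:
    """Exhaustive fitness maximization over the (k%, mu, lambda) grid.

    Returns the best hyperparameters and the full table of evaluated
    combinations (one dict per combination with the aggregate metrics).
    With ``skip_failures`` a combination whose optimization diverges (the
    manifold term can make the objective unbounded below) is recorded
    with fitness -inf instead of aborting the search.
    """
    grid = grid or GridSpec()
    base = base or HyperParams()
    table: list[dict] = []
    best: tuple[float, HyperParams] | None = None
    for k_percent, mu, lam in itertools.product(grid.k_percents, grid.mus, grid.lams):
        hyper = HyperParams(
            k_percent=k_percent,
            mu=mu,
            lam=lam,
            epsilon=base.epsilon,
            max_iter=base.max_iter,
            seed=base.seed,
            use_normalized_similarity=base.use_normalized_similarity,
            update_variant=base.update_variant,
        )
        try:
            report = cross_validate(R, simC, simD, hyper, n_folds, n_repeats, seed)
        except (ValueError, FloatingPointError):
            if not skip_failures:
                raise
            logger.warning(
                "grid point k%%=%s mu=%s lambda=%s diverged; skipped",
                k_percent,
                mu,
                lam,
            )
            table.append(
                {
                    "k_percent": k_percent,
                    "mu": mu,
                    "lam": lam,
                    "rmse": float("nan"),
                    "r2": float("nan"),
                    "pcc": float("nan"),
                    "fitness": float("-inf"),
                }
            )
            continue
        row = {
            "k_percent": k_percent,
            "mu": mu,
            "lam": lam,
            "rmse": report.aggregate_rmse,
            "r2": report.aggregate_r2,
            "pcc": report.aggregate_pcc,
            "fitness": report.fitness,
        }
        table.append(row)
        if best is None or report.fitness > best[0]:
            best = (report.fitness, hyper)
    if best is None:
        raise ValueError("every grid combination diverged")
    return best[1], table


def drugwise_pcc(real: ResponseMatrix, predicted: np.ndarray) -> dict[str, float]:
    """Per-drug correlation of predictions with observed responses.

    Drugs with fewer than 2 observed (and predicted) cells are omitted
    with a warning.  NaNs in ``predicted`` are treated as absent.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != real.values.shape:
        raise ValueError(
            f"prediction shape {predicted.shape} != response shape {real.values.shape}"
        )
    out: dict[str, float] = {}
    for j, drug in enumerate(real.drug_ids):
        usable = real.observed_mask[:, j] & np.isfinite(predicted[:, j])
        if usable.sum() < 2:
            logger.warning("drug %r observed in <2 cells; omitted from drug-wise PCC", drug)
            continue
        truth = real.values[usable, j]
        pred = predicted[usable, j]
        if truth.std() == 0.0 or pred.std() == 0.0:
            logger.warning("drug %r has a constant vector; omitted from drug-wise PCC", drug)
            continue
        out[drug] = pcc_metric(truth, pred)
    return out


def knn_baseline(
    R: ResponseMatrix,
    simC: SimilarityMatrix,
    simD: SimilarityMatrix,
    test_pairs: list[tuple[int, int]] | np.ndarray,
    k_neighbors: int = 1,
) -> np.ndarray:
    """Nearest-neighbour regression baseline over pair feature vectors.

    A pair (i, j) is featurized as the concatenation of row i of the
    cell-line similarity with column j of the drug similarity; a test
    pair's prediction is the mean response of its ``k_neighbors`` nearest
    training pairs under Euclidean distance.
    """
    from sklearn.neighbors import KNeighborsRegressor

    SC = simC.reindex(R.cell_ids).values
    SD = simD.reindex(R.drug_ids).values
    test_pairs = np.asarray(test_pairs, dtype=int)
    mask = R.observed_mask.copy()
    mask[test_pairs[:, 0], test_pairs[:, 1]] = False
    train_pairs = np.argwhere(mask)
    if len(train_pairs) == 0:
        raise ValueError("no training pairs for the KNN baseline")

    def featurize(pairs: np.ndarray) -> np.ndarray:
        return np.hstack([SC[pairs[:, 0]], SD[:, pairs[:, 1]].T])

    model = KNeighborsRegressor(n_neighbors=min(k_neighbors, len(train_pairs)))
    model.fit(featurize(train_pairs), R.values[train_pairs[:, 0], train_pairs[:, 1]])
    return model.predict(featurize(test_pairs))
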