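"""Similarity-constrained low-rank factorization of the response matrix.

The response matrix R (cell lines x drugs, log IC50, possibly masked) is
approximated by P Q^T with P in R^{n x k}, Q in R^{m x k}.  The objective

    L = 1/2 sum_{(i,j) observed} (r_ij - p_i . q_j)^2
        + mu/2 (sum_i ||p_i||^2 + sum_j ||q_j||^2)
        + lam/2 (sum_{i,j} ||p_i - p_j||^2 SimC(i,j)
                 + sum_{i,j} ||q_i - q_j||^2 SimD(i,j))

couples the reconstruction of observed entries with a ridge penalty and a
manifold penalty that keeps latent vectors of similar entities close.
Each row subproblem in p_i (and q_j) is an unconstrained quadratic, so a
single Newton step lands on its exact minimizer; P and Q are updated
alternately until the predicted matrix stops moving.  A second run on the
transposed problem, warm-started from the first run's factors, is
averaged in to form the final prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from adrml.io import ResponseMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

UPDATE_VARIANTS = ("derived", "as_printed")

#: Eigenvalue floor below which a block Hessian gets a ridge safeguard.
_HESSIAN_EIG_FLOOR = 1e-10
_HESSIAN_RIDGE = 1e-8


@dataclass
class HyperParams:
    """Hyperparameters of the factorization.

    k_percent : latent dimension as a percentage of min(n cells, n drugs);
        k = round(k_percent/100 * min(n, m)), at least 1.  Default 70.
    mu : ridge regularization coefficient on the latent factors.  Default 8.
    lam : similarity-conservation (manifold) coefficient.  Default 4.
    epsilon : convergence tolerance on the Frobenius norm of the change in
        the predicted matrix between iterations.  Default 0.01.
    max_iter : iteration cap.  Default 200.
    seed : seed for the random initialization of the factors.
    use_normalized_similarity : pass the similarity matrices through the
        symmetric normalized Laplacian before fitting (the default
        pipeline behaviour); raw similarities are used when False.
    update_variant : 'derived' solves each row subproblem exactly
        (zero-gradient solution); 'as_printed' keeps the entity's own
        previous latent vector in the update numerator instead of its
        neighbours'.
    treat_mask_as_full : ignore the observed mask and fit every entry
        (requires a fully finite response matrix).
    """

    k_percent: float = 70.0
    mu: float = 8.0
    lam: float = 4.0
    epsilon: float = 0.01
    max_iter: int = 200
    seed: int = 0
    use_normalized_similarity: bool = True
    update_variant: str = "derived"
    treat_mask_as_full: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.k_percent <= 100:
            raise ValueError(f"k_percent must lie in (0, 100], got {self.k_percent}")
        if self.mu < 0 or self.lam < 0:
            raise ValueError("mu and lam must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.update_variant not in UPDATE_VARIANTS:
            raise ValueError(
                f"update_variant must be one of {UPDATE_VARIANTS}, got "
                f"{self.update_variant!r}"
            )

    def latent_dim(self, n: int, m: int) -> int:
        """Latent dimension k derived from the matrix shape."""
        return max(1, round(self.k_percent / 100.0 * min(n, m)))


@dataclass
class LatentFactors:
    """Fitted factor matrices with diagnostics.

    P holds one latent row vector per cell line, Q one per drug;
    ``loss_trace`` records the objective after initialization and after
    every alternating sweep.
    """

    P: np.ndarray
    Q: np.ndarray
    hyper: HyperParams
    n_iterations: int = 0
    loss_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def predict(self) -> np.ndarray:
        return self.P @ self.Q.T


@dataclass
class PredictionResult:
    """Forward, transpose-run, and averaged predicted response matrices."""

    forward: np.ndarray
    reverse: np.ndarray
    combined: np.ndarray
    forward_factors: LatentFactors | None = None
    reverse_factors: LatentFactors | None = None


def _sim_values(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(sim, SimilarityMatrix):
        return sim.values
    return np.asarray(sim, dtype=float)


def _mask_of(R: ResponseMatrix, treat_mask_as_full: bool = False) -> np.ndarray:
    if treat_mask_as_full:
        if not np.all(np.isfinite(R.values)):
            raise ValueError("treat_mask_as_full requires a fully finite response matrix")
        return np.ones_like(R.observed_mask, dtype=bool)
    return R.observed_mask


def _manifold_term(X: np.ndarray, S: np.ndarray) -> float:
    """sum_{i,j} ||x_i - x_j||^2 S(i,j) via trace identities."""
    sq = np.sum(X * X, axis=1)
    row = S.sum(axis=1)
    col = S.sum(axis=0)
    cross = float(np.sum(S * (X @ X.T)))
    return float(sq @ row + sq @ col - 2.0 * cross)


def loss(
    R: ResponseMatrix,
    P: np.ndarray,
    Q: np.ndarray,
    simC: SimilarityMatrix | np.ndarray,
    simD: SimilarityMatrix | np.ndarray,
    mu: float,
    lam: float,
    *,
    treat_mask_as_full: bool = False,
) -> float:
    """Objective value at (P, Q); reconstruction runs over observed entries."""
    SC = _sim_values(simC)
    SD = _sim_values(simD)
    n, m = R.values.shape
    if P.shape[0] != n or Q.shape[0] != m or P.shape[1] != Q.shape[1]:
        raise ValueError(
            f"factor shapes {P.shape}, {Q.shape} inconsistent with response {R.values.shape}"
        )
    if SC.shape != (n, n) or SD.shape != (m, m):
        raise ValueError("similarity shapes inconsistent with response matrix")
    mask = _mask_of(R, treat_mask_as_full)
    resid = np.where(mask, R.values - P @ Q.T, 0.0)
    recon = 0.5 * float(np.sum(resid * resid))
    ridge = 0.5 * mu * (float(np.sum(P * P)) + float(np.sum(Q * Q)))
    manifold = 0.5 * lam * (_manifold_term(P, SC) + _manifold_term(Q, SD))
    return recon + ridge + manifold


def _lambda_weights(S: np.ndarray) -> np.ndarray:
    """w_i = sum_{j != i} (S(i,j) + S(j,i)) -- the manifold Hessian scalars."""
    return S.sum(axis=1) + S.sum(axis=0) - 2.0 * np.diag(S)


def gradient_hessian_P(
    i: int,
    R: ResponseMatrix,
    P: np.ndarray,
    Q: np.ndarray,
    simC: SimilarityMatrix | np.ndarray,
    mu: float,
    lam: float,
    *,
    treat_mask_as_full: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the objective with respect to row p_i."""
    SC = _sim_values(simC)
    mask = _mask_of(R, treat_mask_as_full)
    obs = mask[i]
    Qo = Q[obs]
    resid = P[i] @ Qo.T - R.values[i, obs]
    grad = resid @ Qo + mu * P[i]
    w_vec = SC[i] + SC[:, i]
    w_vec = w_vec.copy()
    w_vec[i] = 0.0  # self-pair contributes nothing to the derivative
    grad = grad + lam * (w_vec.sum() * P[i] - w_vec @ P)
    k = P.shape[1]
    hess = Qo.T @ Qo + (mu + lam * w_vec.sum()) * np.eye(k)
    return grad, hess


def gradient_hessian_Q(
    j: int,
    R: ResponseMatrix,
    P: np.ndarray,
    Q: np.ndarray,
    simD: SimilarityMatrix | np.ndarray,
    mu: float,
    lam: float,
    *,
    treat_mask_as_full: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient and Hessian of the objective with respect to row q_j."""
    SD = _sim_values(simD)
    mask = _mask_of(R, treat_mask_as_full)
    obs = mask[:, j]
    Po = P[obs]
    resid = Q[j] @ Po.T - R.values[obs, j]
    grad = resid @ Po + mu * Q[j]
    w_vec = SD[j] + SD[:, j]
    w_vec = w_vec.copy()
    w_vec[j] = 0.0
    grad = grad + lam * (w_vec.sum() * Q[j] - w_vec @ Q)
    k = Q.shape[1]
    hess = Po.T @ Po + (mu + lam * w_vec.sum()) * np.eye(k)
    return grad, hess


def _safeguarded_solve(H: np.ndarray, b: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Minimize the row subproblem 1/2 x H x^T - x . b, guarding indefiniteness.

    The subproblem only has a minimizer when H is positive definite; a
    normalized-Laplacian similarity can push the lambda part of H negative
    and leave genuinely unbounded directions.  The safeguard minimizes
    exactly over the positive-curvature eigendirections and freezes the
    row's current component along directions whose eigenvalue falls below
    a scaled floor.  Each row update therefore never increases the loss
    and the iterates stay bounded; well-posed rows take the plain Newton
    solve.
    """
    k = H.shape[0]
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite block subproblem; factors diverged")
    try:
        chol = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        chol = None
    if chol is not None:
        x = np.linalg.solve(chol.T, np.linalg.solve(chol, b))
        return x
    eigvals, eigvecs = np.linalg.eigh(H)
    floor = max(
        _HESSIAN_RIDGE * (1.0 + abs(float(np.trace(H))) / k),
        _HESSIAN_EIG_FLOOR,
    )
    logger.warning(
        "block Hessian not positive definite (min eig %.3e); freezing "
        "directions with curvature below %.3e",
        eigvals[0],
        floor,
    )
    stable = eigvals > floor
    coeff = eigvecs.T @ b
    z = eigvecs.T @ current
    z_new = np.where(stable, coeff / np.where(stable, eigvals, 1.0), z)
    return eigvecs @ z_new


def _update_block(
    values: np.ndarray,
    mask: np.ndarray,
    X: np.ndarray,
    other: np.ndarray,
    S: np.ndarray,
    mu: float,
    lam: float,
    variant: str,
) -> np.ndarray:
    """One sweep over the rows of X (cells if X=P, drugs if X=Q).

    ``values``/``mask`` must be oriented rows-of-X by columns-of-other.
    """
    n, k = X.shape
    W = S + S.T
    np.fill_diagonal(W, 0.0)
    w_sums = W.sum(axis=1)
    new = X.copy()
    for i in range(n):
        obs = mask[i]
        Oo = other[obs]
        H = Oo.T @ Oo + (mu + lam * w_sums[i]) * np.eye(k)
        if variant == "derived":
            b = values[i, obs] @ Oo + lam * (W[i] @ new)
        else:  # as_printed: own previous row in the numerator
            b = values[i, obs] @ Oo + lam * w_sums[i] * X[i]
        new[i] = _safeguarded_solve(H, b, new[i])
    return new


def update_P(
    R: ResponseMatrix,
    P: np.ndarray,
    Q: np.ndarray,
    simC: SimilarityMatrix | np.ndarray,
    mu: float,
    lam: float,
    variant: str = "derived",
    *,
    treat_mask_as_full: bool = False,
) -> np.ndarray:
    """Newton sweep over the cell-line factor rows.

    With ``variant='derived'`` each p_i jumps to the exact minimizer of
    its quadratic subproblem (the zero-gradient solution); rows updated
    earlier in the sweep feed into later rows through the manifold term.
    """
    mask = _mask_of(R, treat_mask_as_full)
    return _update_block(R.values, mask, P, Q, _sim_values(simC).copy(), mu, lam, variant)


def update_Q(
    R: ResponseMatrix,
    P: np.ndarray,
    Q: np.ndarray,
    simD: SimilarityMatrix | np.ndarray,
    mu: float,
    lam: float,
    variant: str = "derived",
    *,
    treat_mask_as_full: bool = False,
) -> np.ndarray:
    """Newton sweep over the drug factor rows (mirror of :func:`update_P`)."""
    mask = _mask_of(R, treat_mask_as_full)
    return _update_block(R.values.T, mask.T, Q, P, _sim_values(simD).copy(), mu, lam, variant)


def _aligned_similarities(
    R: ResponseMatrix,
    simC: SimilarityMatrix,
    simD: SimilarityMatrix,
    hyper: HyperParams,
) -> tuple[np.ndarray, np.ndarray]:
    from adrml.similarity import normalize_similarity

    simC = simC.reindex(R.cell_ids)
    simD = simD.reindex(R.drug_ids)
    if hyper.use_normalized_similarity:
        if not simC.normalized:
            simC = normalize_similarity(simC)
        if not simD.normalized:
            simD = normalize_similarity(simD)
    return simC.values, simD.values


def _initial_factors(n: int, m: int, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    # Uniform [0, 1) entries: the O(1) scale keeps the initial factor
    # Grams well conditioned (min eigenvalue ~ m/12), which matters when a
    # normalized-Laplacian similarity makes the lambda part of the row
    # Hessians negative -- a smaller init can leave the first sweep
    # indefinite and the iteration divergent.
    rng = np.random.default_rng(seed)
    return rng.random((n, k)), rng.random((m, k))


def fit(
    R: ResponseMatrix,
    simC: SimilarityMatrix,
    simD: SimilarityMatrix,
    hyper: HyperParams | None = None,
    *,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> LatentFactors:
    """Alternating Newton optimization of the factors for one orientation.

    Similarities are aligned to the response labels (and Laplacian
    normalized when the hyperparameters ask for it), factors are seeded
    randomly unless ``init`` supplies warm-start matrices, and sweeps
    over P then Q repeat until the Frobenius norm of the change in the
    predicted matrix drops below ``epsilon``.
    """
    hyper = hyper or HyperParams()
    n, m = R.values.shape
    mask = _mask_of(R, hyper.treat_mask_as_full)
    if not mask.any():
        raise ValueError("response matrix has no observed entries")
    empty_rows = np.nonzero(~mask.any(axis=1))[0]
    empty_cols = np.nonzero(~mask.any(axis=0))[0]
    if empty_rows.size:
        logger.warning(
            "%d cell line(s) have no observed responses (first: %r); their "
            "factors are driven by regularization alone",
            empty_rows.size,
            R.cell_ids[empty_rows[0]],
        )
    if empty_cols.size:
        logger.warning(
            "%d drug(s) have no observed responses (first: %r)",
            empty_cols.size,
            R.drug_ids[empty_cols[0]],
        )
    SC, SD = _aligned_similarities(R, simC, simD, hyper)
    k = hyper.latent_dim(n, m)
    if init is not None:
        P, Q = np.array(init[0], dtype=float), np.array(init[1], dtype=float)
        if P.shape != (n, k) or Q.shape != (m, k):
            raise ValueError(
                f"warm-start shapes {P.shape}, {Q.shape} do not match ({n},{k}), ({m},{k})"
            )
    else:
        P, Q = _initial_factors(n, m, k, hyper.seed)
    trace = [
        loss(R, P, Q, SC, SD, hyper.mu, hyper.lam, treat_mask_as_full=hyper.treat_mask_as_full)
    ]
    pred = P @ Q.T
    converged = False
    iteration = 0
    for iteration in range(1, hyper.max_iter + 1):
        with np.errstate(over="ignore", invalid="ignore"):
            P = _update_block(R.values, mask, P, Q, SC, hyper.mu, hyper.lam, hyper.update_variant)
            if not np.all(np.isfinite(P)):
                raise ValueError(
                    f"factors diverged at iteration {iteration}; the manifold "
                    "term makes this configuration unbounded below"
                )
            Q = _update_block(R.values.T, mask.T, Q, P, SD, hyper.mu, hyper.lam, hyper.update_variant)
            if not np.all(np.isfinite(Q)):
                raise ValueError(
                    f"factors diverged at iteration {iteration}; the manifold "
                    "term makes this configuration unbounded below"
                )
            current = loss(
                R, P, Q, SC, SD, hyper.mu, hyper.lam, treat_mask_as_full=hyper.treat_mask_as_full
            )
        if not np.isfinite(current):
            raise ValueError(f"non-finite loss at iteration {iteration}")
        trace.append(current)
        new_pred = P @ Q.T
        delta = float(np.linalg.norm(new_pred - pred))
        pred = new_pred
        logger.debug("iteration %d: loss %.6g, prediction change %.3e", iteration, current, delta)
        if delta < hyper.epsilon:
            converged = True
            break
    return LatentFactors(P, Q, hyper, n_iterations=iteration, loss_trace=trace, converged=converged)


def predict_dual(
    R: ResponseMatrix,
    simC: SimilarityMatrix,
    simD: SimilarityMatrix,
    hyper: HyperParams | None = None,
) -> PredictionResult:
    """Two-run prediction: fit R, re-fit R^T warm-started, average.

    The transposed run swaps the roles of cell lines and drugs (and of the
    two similarity matrices) and initializes its factors from the first
    run's final Q and P.  The combined prediction is the elementwise mean
    of the two reconstructions, defined for every (cell, drug) pair,
    observed or not.
    """
    hyper = hyper or HyperParams()
    forward_fit = fit(R, simC, simD, hyper)
    forward = forward_fit.predict()
    Rt = ResponseMatrix(
        list(R.drug_ids), list(R.cell_ids), R.values.T.copy(), R.observed_mask.T.copy()
    )
    reverse_fit = fit(Rt, simD, simC, hyper, init=(forward_fit.Q, forward_fit.P))
    reverse = reverse_fit.predict().T
    combined = 0.5 * (forward + reverse)
    return PredictionResult(forward, reverse, combined, forward_fit, reverse_fit)
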