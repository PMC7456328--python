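"""Benchmark purification, pathway scoring, and sensitivity calling.

Three post-hoc analyses around the factorization:

* redundancy removal -- within each tissue type, cell lines that are more
  similar than the tissue's third similarity quartile to a large share of
  their peers are excluded, yielding a purified benchmark;
* pathway activity -- per cell line and gene set, the summed log fold
  change of expression against each gene's across-cell median, correlated
  against predicted drug responses to associate drugs with pathways;
* sensitive/resistant calling -- per drug, the unmeasured cell lines are
  quartiled by predicted log IC50; the lowest quartile is called
  sensitive, the highest resistant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from adrml.io import FeatureTable, GeneSetCollection, SimilarityMatrix, TissueAnnotation
from adrml.similarity import pcc

logger = logging.getLogger(__name__)


@dataclass
class RedundancyReport:
    """Outcome of tissue-wise redundancy removal."""

    per_tissue_quantiles: dict[str, tuple[float, float, float, float, float]]
    kept: list[str]
    removed: list[str]
    theta: float
    similarity_kind: str | None = None


@dataclass
class ActivityScores:
    """Cell x pathway activity matrix after the gene-coverage filter."""

    cell_ids: list[str]
    pathway_ids: list[str]
    values: np.ndarray
    retained_pathways: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.pathway_ids)):
            raise ValueError("activity matrix shape inconsistent with labels")
        if not self.retained_pathways:
            self.retained_pathways = list(self.pathway_ids)


def _tissue_pairwise(
    S: SimilarityMatrix, cells: list[str]
) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(S.entity_ids)}
    try:
        idx = [pos[c] for c in cells]
    except KeyError as exc:
        raise KeyError(f"cell {exc.args[0]!r} absent from similarity matrix") from None
    sub = S.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sub[iu]


def tissue_similarity_quantiles(
    S: SimilarityMatrix, tissues: TissueAnnotation
) -> dict[str, tuple[float, float, float, float, float]]:
    """Five-number summary (Q0..Q4) of within-tissue pairwise similarities.

    Quantiles use linear interpolation between order statistics of the
    off-diagonal upper-triangle values; tissues with a single cell have no
    pairs and are absent from the result.
    """
    out: dict[str, tuple[float, float, float, float, float]] = {}
    for tissue, cells in tissues.by_tissue().items():
        if len(cells) < 2:
            continue
        vals = _tissue_pairwise(S, cells)
        qs = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
        out[tissue] = tuple(float(q) for q in qs)
    return out


def remove_redundant(
    S: SimilarityMatrix, tissues: TissueAnnotation, theta: float = 0.20
) -> RedundancyReport:
    """Exclude cell lines over-similar to their tissue peers.

    Cell c in tissue t (with n_t annotated cells) is removed iff the
    number of *other* cells of t whose similarity to c strictly exceeds
    the tissue's third quartile Q3(t) is strictly greater than
    theta * n_t.  All removals are decided simultaneously from the
    original tissue composition; singleton tissues are always kept.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    quantiles = tissue_similarity_quantiles(S, tissues)
    pos = {lab: i for i, lab in enumerate(S.entity_ids)}
    kept: list[str] = []
    removed: list[str] = []
    for cell in tissues.mapping:
        if cell not in pos:
            raise KeyError(f"cell {cell!r} absent from similarity matrix")
    by_tissue = tissues.by_tissue()
    for tissue, cells in by_tissue.items():
        if len(cells) < 2:
            kept.extend(cells)
            continue
        q3 = quantiles[tissue][3]
        n_t = len(cells)
        idx = [pos[c] for c in cells]
        sub = S.values[np.ix_(idx, idx)]
        for local, cell in enumerate(cells):
            over = sum(
                1 for other in range(n_t) if other != local and sub[local, other] > q3
            )
            if over > theta * n_t:
                removed.append(cell)
            else:
                kept.append(cell)
    return RedundancyReport(
        per_tissue_quantiles=quantiles,
        kept=kept,
        removed=removed,
        theta=theta,
        similarity_kind=S.kind,
    )


def threshold_sweep(
    S: SimilarityMatrix, tissues: TissueAnnotation, thetas: list[float]
) -> dict[float, int]:
    """Kept-cell counts of :func:`remove_redundant` across thresholds."""
    if not thetas:
        raise ValueError("thetas must be non-empty")
    return {theta: len(remove_redundant(S, tissues, theta).kept) for theta in thetas}


def pathway_activity(
    expr: FeatureTable,
    sets: GeneSetCollection,
    max_missing_fraction: float = 0.10,
    pseudo_count: float = 0.0,
) -> ActivityScores:
    """Per-cell pathway activity as summed log fold change vs. gene medians.

    Pathways with more than ``max_missing_fraction`` of their genes absent
    from the expression table are dropped; for retained pathways, absent
    genes are skipped in the sum.  AS(c, p) = sum over present genes g of
    ln(EXPR(c, g) / median over cells of EXPR(., g)).  Expression must be
    strictly positive (a ``pseudo_count`` can be added to tolerate zeros).
    """
    gene_pos = {g: j for j, g in enumerate(expr.feature_ids)}
    retained: list[str] = []
    columns: list[np.ndarray] = []
    X = expr.values + pseudo_count
    for name, genes in sets.items():
        present = [g for g in genes if g in gene_pos]
        if len(genes) - len(present) > max_missing_fraction * len(genes):
            logger.info("pathway %r dropped: insufficient gene coverage", name)
            continue
        idx = [gene_pos[g] for g in present]
        sub = X[:, idx]
        nonpos = np.argwhere(sub <= 0.0)
        if nonpos.size:
            i, j = nonpos[0]
            raise ValueError(
                f"non-positive expression for cell {expr.entity_ids[i]!r}, "
                f"gene {present[j]!r}; log fold change undefined"
            )
        medians = np.median(sub, axis=0)
        columns.append(np.log(sub / medians).sum(axis=1))
        retained.append(name)
    values = (
        np.column_stack(columns) if columns else np.empty((expr.n_entities, 0))
    )
    return ActivityScores(list(expr.entity_ids), retained, values, retained)


def drug_pathway_association(
    predicted: np.ndarray,
    activity: ActivityScores,
    drug_ids: list[str] | None = None,
) -> np.ndarray:
    """Drugs x pathways correlation between predictions and activity.

    Entry (i, j) is the Pearson correlation of drug i's predicted
    response across cells with pathway j's activity across the same
    cells; a zero-variance column yields NaN with a warning.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape[0] != len(activity.cell_ids):
        raise ValueError(
            f"{predicted.shape[0]} predicted rows vs {len(activity.cell_ids)} "
            "activity cells; align by label first"
        )
    if predicted.shape[0] < 2:
        raise ValueError("association needs at least 2 cells")
    n_drugs = predicted.shape[1]
    n_paths = len(activity.pathway_ids)
    out = np.full((n_drugs, n_paths), np.nan)
    for i in range(n_drugs):
        for j in range(n_paths):
            x = predicted[:, i]
            y = activity.values[:, j]
            if x.std() == 0.0 or y.std() == 0.0:
                name = drug_ids[i] if drug_ids else i
                logger.warning(
                    "constant vector for drug %r / pathway %r; association NaN",
                    name,
                    activity.pathway_ids[j],
                )
                continue
            out[i, j] = pcc(x, y)
    return out


def call_sensitivity(
    predicted: np.ndarray,
    observed_mask: np.ndarray,
    cell_ids: list[str],
    drug_ids: list[str],
) -> dict[str, tuple[list[str], list[str]]]:
    """Quartile-based sensitive/resistant calls among unmeasured cells.

    Per drug, cells without an observed response are ranked by predicted
    log IC50 (ascending; ties broken by cell-label order) and split into
    four near-equal groups, earlier groups taking the remainder.  The
    lowest group is called sensitive, the highest resistant.  Drugs with
    fewer than 4 unmeasured cells yield empty lists with a warning.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if predicted.shape != observed_mask.shape:
        raise ValueError("prediction and mask shapes differ")
    if predicted.shape != (len(cell_ids), len(drug_ids)):
        raise ValueError("labels inconsistent with matrix shape")
    calls: dict[str, tuple[list[str], list[str]]] = {}
    for j, drug in enumerate(drug_ids):
        unknown = np.nonzero(~observed_mask[:, j])[0]
        if len(unknown) < 4:
            logger.warning(
                "drug %r has %d unmeasured cells (<4); no sensitivity call",
                drug,
                len(unknown),
            )
            calls[drug] = ([], [])
            continue
        order = sorted(unknown, key=lambda i: (predicted[i, j], cell_ids[i]))
        groups = np.array_split(np.array(order), 4)
        sensitive = [cell_ids[i] for i in groups[0]]
        resistant = [cell_ids[i] for i in groups[-1]]
        calls[drug] = (sensitive, resistant)
    return calls
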