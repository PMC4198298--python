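"""Tree-ensemble gene regulatory network inference (GENIE3 procedure).

For each target gene j, a randomized regression-tree ensemble predicts the
target's (unit-variance standardized) expression from all other genes across
samples; the weight w_ij of the directed link i -> j is regulator i's total
impurity (variance) reduction, averaged over trees and not renormalized, so
a target's incoming weights sum to the ensemble's explained-variance mass.
The sum of all entries of the weighted adjacency matrix is the coherence
statistic used to quantify how strongly a gene set co-varies.

Ensemble defaults follow the original formulation: random forests of 100
trees with sqrt(n_regulators) candidate regulators per split and a minimum
leaf size of 5 (the classic regression-forest default).  The leaf size
matters: fully-grown trees explain essentially all in-sample variance of
*any* target, signal or noise, which would flatten the coherence statistic.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ValidationError

__all__ = ["infer_adjacency", "coherence_statistic"]

logger = logging.getLogger(__name__)


def _unnormalized_importances(forest: RandomForestRegressor, n_features: int) -> np.ndarray:
    """Mean per-tree variance reduction per regulator, without the usual
    sum-to-one normalization (weights must stay comparable across targets)."""
    total = np.zeros(n_features)
    for est in forest.estimators_:
        total += est.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_)


def infer_adjacency(
    expression: pd.DataFrame,
    *,
    n_trees: int = 100,
    max_features: int | float | str = "sqrt",
    min_samples_leaf: int = 5,
    seed: int | None = None,
    regulators: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Infer the weighted adjacency matrix of a gene set.

    Parameters
    ----------
    expression
        Genes x samples matrix restricted to the gene set of interest
        (>= 3 genes, >= 10 samples).
    n_trees, max_features
        Ensemble size and candidate-regulator subset per split.
    seed
        Seeds the per-target forests reproducibly.  Each target's forest
        seed is derived from (seed, gene id), so the result is equivariant
        under permutations of the gene order.
    regulators
        Optional subset of genes allowed as regulators (default: all).

    Returns
    -------
    DataFrame ``w`` with regulators as rows and targets as columns;
    ``w.loc[i, j]`` is the importance of link i -> j, the diagonal is 0, and
    constant genes contribute zero rows/columns (with a warning).
    """
    input_order = list(expression.index)
    n_genes, n_samples = expression.shape
    if n_genes < 3:
        raise ValidationError("network inference needs >= 3 genes")
    if n_samples < 10:
        raise ValidationError("network inference needs >= 10 samples")
    if len(set(input_order)) != n_genes:
        raise ValidationError("duplicate gene ids in expression matrix")
    # canonical gene order so results do not depend on input row order
    genes = sorted(input_order)
    expression = expression.loc[genes]
    values = expression.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "infer_adjacency: %d constant genes get zero weights", int(constant.sum())
        )
    reg_mask = np.ones(n_genes, dtype=bool) if regulators is None else np.isin(
        genes, list(regulators)
    )
    reg_mask &= ~constant

    w = np.zeros((n_genes, n_genes))
    for j in range(n_genes):
        if constant[j]:
            continue
        candidates = np.flatnonzero(reg_mask & (np.arange(n_genes) != j))
        if candidates.size == 0:
            continue
        y = (values[j] - values[j].mean()) / sd[j]  # unit-variance target
        X = values[candidates].T
        digest = hashlib.sha256(f"{seed}:{genes[j]}".encode()).digest()
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int.from_bytes(digest[:4], "big") % (2**31),
            n_jobs=1,
        )
        forest.fit(X, y)
        w[candidates, j] = _unnormalized_importances(forest, candidates.size)
    out = pd.DataFrame(w, index=pd.Index(genes, name="regulator"),
                       columns=pd.Index(genes, name="target"))
    return out.loc[input_order, input_order]


def coherence_statistic(w: pd.DataFrame | np.ndarray) -> float:
    """Sum of all entries of the weighted adjacency matrix.

    The diagonal is zero by construction, so this is the total weight over
    directed links — larger means more mutually predictable expression.
    """
    values = w.to_numpy() if isinstance(w, pd.DataFrame) else np.asarray(w, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("adjacency matrix must be square")
    if not np.isfinite(values).all():
        raise ValidationError("adjacency matrix has non-finite entries")
    if (values < 0).any():
        raise ValidationError("adjacency weights must be nonnegative")
    return float(values.sum())
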