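"""Tree-agnostic baselines for combining ortholog scores.

The stacking baseline feeds the raw vector of per-species scores to a
small feed-forward network, ignoring the phylogeny entirely; comparing
it against the tree-aware model quantifies the value of the tree.  The
architecture and L2 penalty are chosen from a fixed grid by 10-fold
cross-validated AUPR.  A mean-of-scores baseline (plain average of the
non-missing ortholog scores) is also provided.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import average_precision_score
from sklearn.neural_network import MLPClassifier

from .score_table import OrthologScoreTable

__all__ = [
    "ARCHITECTURE_GRID",
    "L2_GRID",
    "StackingModel",
    "fit_stacking",
    "predict_stacking",
    "mean_of_scores",
    "focal_scores",
]

ARCHITECTURE_GRID: Tuple[Tuple[int, ...], ...] = ((32,), (100,), (64, 32))
L2_GRID: Tuple[float, ...] = (0.1, 1.0, 10.0)


@dataclass
class StackingModel:
    """A fitted MLP over the per-species score vector."""

    input_species_order: List[str]
    architecture: Tuple[int, ...]
    l2_penalty: float
    imputation_value: float
    cv_aupr: float
    mlp: MLPClassifier = field(repr=False)


def _fold_of(example_id: str, seed: int, n_folds: int) -> int:
    """Deterministic fold assignment from the example id and seed."""
    digest = hashlib.md5(f"{seed}:{example_id}".encode()).hexdigest()
    return int(digest, 16) % n_folds


def _design_matrix(
    table: OrthologScoreTable, species_order: List[str], imputation_value: float
) -> np.ndarray:
    X = table.scores.reindex(columns=species_order).to_numpy(dtype=float)
    return np.where(np.isnan(X), imputation_value, X)


def _new_mlp(architecture, l2_penalty, seed, max_iter) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=architecture,
        alpha=l2_penalty,
        random_state=seed,
        max_iter=max_iter,
    )


def fit_stacking(
    train: OrthologScoreTable,
    seed: int,
    *,
    n_folds: int = 10,
    imputation_value: float = 0.5,
    max_iter: int = 300,
) -> StackingModel:
    """Grid-search the MLP over architectures and L2 penalties.

    Every (architecture, penalty) pair from the fixed grids is evaluated
    by mean cross-validated AUPR; folds are a deterministic function of
    example id and seed, so permuting the training rows cannot change
    the winner.  The winner is refitted on the full training set.
    Missing scores are imputed with ``imputation_value`` (0.5, the
    uninformative midpoint of a sigmoid output).
    """
    if train.labels is None:
        raise ValueError("training table must carry labels")
    # canonical row order so CV and refit are invariant to input row order
    order = sorted(train.example_ids)
    train = train.subset(order)
    y = train.labels.to_numpy()
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate training set: both classes must be present")
    min_class = min(n_pos, n_neg)
    if min_class < n_folds:
        warnings.warn(
            f"only {min_class} examples in the rarer class; reducing folds "
            f"from {n_folds} to {max(2, min_class)}",
            stacklevel=2,
        )
        n_folds = max(2, min_class)

    species_order = list(train.species)
    X = _design_matrix(train, species_order, imputation_value)
    folds = np.array([_fold_of(eid, seed, n_folds) for eid in train.example_ids])

    best: Optional[Tuple[float, Tuple[int, ...], float]] = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for architecture in ARCHITECTURE_GRID:
            for l2_penalty in L2_GRID:
                fold_auprs = []
                for k in range(n_folds):
                    val = folds == k
                    if val.all() or not val.any() or len(np.unique(y[val])) < 2:
                        continue  # fold unusable for AUPR
                    if len(np.unique(y[~val])) < 2:
                        continue
                    mlp = _new_mlp(architecture, l2_penalty, seed, max_iter)
                    mlp.fit(X[~val], y[~val])
                    proba = mlp.predict_proba(X[val])[:, 1]
                    fold_auprs.append(average_precision_score(y[val], proba))
                if not fold_auprs:
                    continue
                mean_aupr = float(np.mean(fold_auprs))
                if best is None or mean_aupr > best[0]:
                    best = (mean_aupr, architecture, l2_penalty)
        if best is None:
            raise ValueError("no usable cross-validation fold (classes too sparse)")
        cv_aupr, architecture, l2_penalty = best
        final = _new_mlp(architecture, l2_penalty, seed, max_iter)
        final.fit(X, y)
    return StackingModel(
        input_species_order=species_order,
        architecture=architecture,
        l2_penalty=l2_penalty,
        imputation_value=imputation_value,
        cv_aupr=cv_aupr,
        mlp=final,
    )


def predict_stacking(model: StackingModel, table: OrthologScoreTable) -> np.ndarray:
    """Probability-like score per example, in input row order."""
    missing = set(model.input_species_order) - set(table.species)
    if missing:
        raise ValueError(f"table lacks species the model was trained on: {sorted(missing)}")
    X = _design_matrix(table, model.input_species_order, model.imputation_value)
    return model.mlp.predict_proba(X)[:, 1]


def mean_of_scores(table: OrthologScoreTable) -> np.ndarray:
    """Plain average of each example's non-missing scores (tree-blind)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(table.scores.to_numpy(dtype=float), axis=1)
    return np.where(np.isnan(means), 0.5, means)


def focal_scores(table: OrthologScoreTable, focal: str) -> np.ndarray:
    """The base predictor's focal-species score alone (missing -> 0.5)."""
    if focal not in table.species:
        raise ValueError(f"focal species {focal!r} not in table")
    vals = table.scores[focal].to_numpy(dtype=float)
    return np.where(np.isnan(vals), 0.5, vals)
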