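"""The phylogenetic score-aggregation model.

Given a base predictor's scores on a focal sequence and its orthologs,
the model treats the focal label ``Y`` as the root of the (rerooted)
species tree and factorizes the joint score likelihood along the edges:

    P[s_1, ..., s_n | Y] = P[s_1 | Y] * prod_{(p,c) in edges} P[s_c | s_p, Y]

with ``s_1`` the focal score.  All distributions are 12-bin multinomials
(score rounded to one decimal + a missing bin) estimated from labeled
training examples with a pseudocount ``epsilon``, one conditional table
per edge -- so the evolutionary distance of an edge enters implicitly
through its own table.  The aggregated score is the log-likelihood
ratio

    score = log P[s_1|Y=1]/P[s_1|Y=0]
            + alpha * sum_edges log P[s_c|s_p,Y=1]/P[s_c|s_p,Y=0]

(natural log; alpha down-weights the ortholog evidence), and an example
is called positive iff the score is strictly greater than zero.
Missing scores contribute nothing to the sum at predict time by
default; at fit time they populate the dedicated missing bin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .score_table import MISSING_BIN, N_BINS, OrthologScoreTable
from .tree import PhyloTree, parse_newick, reroot_at

__all__ = [
    "PhyloPGMModel",
    "PredictionResult",
    "ModelFormatError",
    "fit",
    "score_example",
    "score_table",
    "edge_llr_terms",
    "serialize_model",
    "deserialize_model",
    "select_hyperparameters",
]

_FORMAT_VERSION = "phylopgm-model/1"


class ModelFormatError(ValueError):
    """Raised when a serialized model document does not match the schema."""


@dataclass(frozen=True)
class PredictionResult:
    example_id: str
    phylopgm_score: float
    root_llr: float
    branch_llr_sum: float
    predicted_label: int


@dataclass
class PhyloPGMModel:
    """Fitted probability tables over a tree rooted at the focal species.

    ``root_marginal[y, b]`` is P[s_focal = bin b | Y = y]; for each edge
    (p, c), ``edge_tables[(p, c)][y, bp, bc]`` is P[s_c = bc | s_p = bp,
    Y = y].  ``log_prior_ratio`` is log P[Y=1]/P[Y=0], zero for the
    default uniform class prior (it then cancels from the ratio).
    """

    tree: PhyloTree
    focal: str
    epsilon: float
    alpha: float
    root_marginal: np.ndarray  # (2, 12)
    edge_tables: Dict[Tuple[str, str], np.ndarray]  # (2, 12, 12)
    log_prior_ratio: float = 0.0

    def __post_init__(self) -> None:
        assert self.tree.root == self.focal
        np.testing.assert_allclose(self.root_marginal.sum(axis=1), 1.0, atol=1e-9)
        for tbl in self.edge_tables.values():
            np.testing.assert_allclose(tbl.sum(axis=2), 1.0, atol=1e-9)

    @property
    def node_order(self) -> List[str]:
        return list(self.tree.preorder())


def _conditional_from_counts(joint: np.ndarray, epsilon: float) -> np.ndarray:
    """(12, 12) joint counts -> P[child bin | parent bin] with pseudocounts."""
    denom = joint.sum(axis=1, keepdims=True) + N_BINS * epsilon
    return (joint + epsilon) / denom


def fit(
    train: OrthologScoreTable,
    tree: PhyloTree,
    epsilon: float = 1.0,
    alpha: float = 0.1,
    *,
    focal: Optional[str] = None,
    class_prior: Optional[Tuple[float, float]] = None,
) -> PhyloPGMModel:
    """Estimate the root marginal and per-edge conditional tables.

    ``tree`` is rerooted at ``focal`` (default: its current root) before
    estimation.  Counts are accumulated over discretized bins, missing
    scores landing in the missing bin so every table remains a proper
    12-bin multinomial.  ``epsilon`` must be strictly positive so all
    probabilities are strictly positive.  ``class_prior``, if given, is
    (P[Y=0], P[Y=1]) and adds log P1/P0 to every score; the default is
    the uniform prior, which cancels.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if train.labels is None:
        raise ValueError("training table must carry labels")
    focal = focal if focal is not None else tree.root
    if tree.root != focal:
        tree = reroot_at(tree, focal)

    order = list(tree.preorder())
    col = {name: i for i, name in enumerate(order)}
    bins = train.bins_for(order)
    y = train.labels.to_numpy()
    if len(y) == 0:
        warnings.warn("empty training set: all tables are uniform", stacklevel=2)

    root_marginal = np.empty((2, N_BINS))
    for yv in (0, 1):
        fb = bins[y == yv, col[focal]]
        counts = np.bincount(fb, minlength=N_BINS).astype(float)
        root_marginal[yv] = (counts + epsilon) / (len(fb) + N_BINS * epsilon)

    edge_tables: Dict[Tuple[str, str], np.ndarray] = {}
    for parent, child, _length in tree.edges():
        tbl = np.empty((2, N_BINS, N_BINS))
        for yv in (0, 1):
            mask = y == yv
            joint = np.zeros((N_BINS, N_BINS))
            np.add.at(joint, (bins[mask, col[parent]], bins[mask, col[child]]), 1.0)
            tbl[yv] = _conditional_from_counts(joint, epsilon)
        edge_tables[(parent, child)] = tbl

    log_prior_ratio = 0.0
    if class_prior is not None:
        p0, p1 = class_prior
        if p0 <= 0 or p1 <= 0:
            raise ValueError("class prior probabilities must be > 0")
        log_prior_ratio = float(np.log(p1) - np.log(p0))

    return PhyloPGMModel(
        tree=tree,
        focal=focal,
        epsilon=float(epsilon),
        alpha=float(alpha),
        root_marginal=root_marginal,
        edge_tables=edge_tables,
        log_prior_ratio=log_prior_ratio,
    )


def _score_bins(
    model: PhyloPGMModel, bins: np.ndarray, missing: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core scorer over a (n_examples, n_nodes) bin matrix.

    Returns (total score, root LLR, unweighted branch LLR sum).
    ``missing`` is ``"skip"`` (missing-bin terms contribute 0, the
    default reading of "missing values are ignored") or ``"bin"``
    (missing scores are pushed through the tables as bin 11).
    """
    if missing not in ("skip", "bin"):
        raise ValueError(f"missing must be 'skip' or 'bin', got {missing!r}")
    col = {name: i for i, name in enumerate(model.node_order)}
    fb = bins[:, col[model.focal]]
    root_llr = np.log(model.root_marginal[1, fb]) - np.log(model.root_marginal[0, fb])
    if missing == "skip":
        root_llr = np.where(fb == MISSING_BIN, 0.0, root_llr)

    branch = np.zeros(len(bins))
    for (parent, child), tbl in model.edge_tables.items():
        pb = bins[:, col[parent]]
        cb = bins[:, col[child]]
        term = np.log(tbl[1, pb, cb]) - np.log(tbl[0, pb, cb])
        if missing == "skip":
            term = np.where((pb == MISSING_BIN) | (cb == MISSING_BIN), 0.0, term)
        branch += term
    total = root_llr + model.alpha * branch + model.log_prior_ratio
    return total, root_llr, branch


def score_table(
    model: PhyloPGMModel,
    table: OrthologScoreTable,
    *,
    missing: str = "skip",
) -> List[PredictionResult]:
    """Score every example of a table; order matches the input."""
    bins = table.bins_for(model.node_order)
    total, root_llr, branch = _score_bins(model, bins, missing)
    return [
        PredictionResult(
            example_id=str(eid),
            phylopgm_score=float(total[i]),
            root_llr=float(root_llr[i]),
            branch_llr_sum=float(branch[i]),
            predicted_label=int(total[i] > 0.0),
        )
        for i, eid in enumerate(table.example_ids)
    ]


def score_example(
    model: PhyloPGMModel,
    example: OrthologScoreTable,
    *,
    missing: str = "skip",
) -> PredictionResult:
    """Score a single-row table (convenience wrapper over score_table)."""
    if example.n_examples != 1:
        raise ValueError(f"expected exactly 1 example, got {example.n_examples}")
    return score_table(model, example, missing=missing)[0]


def scores_array(
    model: PhyloPGMModel, table: OrthologScoreTable, *, missing: str = "skip"
) -> np.ndarray:
    """Just the aggregated scores as a float array (for ranking metrics)."""
    total, _, _ = _score_bins(model, table.bins_for(model.node_order), missing)
    return total


def edge_llr_terms(
    model: PhyloPGMModel,
    table: OrthologScoreTable,
    *,
    missing: str = "skip",
) -> Tuple[List[Tuple[str, str]], np.ndarray, np.ndarray]:
    """Per-example, per-edge log-likelihood-ratio terms (unweighted by alpha).

    Returns (edge list, terms matrix (n_examples, n_edges), boolean
    contribution mask -- False where the term was skipped because an
    endpoint score was missing).
    """
    bins = table.bins_for(model.node_order)
    col = {name: i for i, name in enumerate(model.node_order)}
    edges = [(p, c) for p, c, _ in model.tree.edges()]
    terms = np.zeros((len(bins), len(edges)))
    contributed = np.ones((len(bins), len(edges)), dtype=bool)
    for j, (parent, child) in enumerate(edges):
        tbl = model.edge_tables[(parent, child)]
        pb = bins[:, col[parent]]
        cb = bins[:, col[child]]
        term = np.log(tbl[1, pb, cb]) - np.log(tbl[0, pb, cb])
        if missing == "skip":
            skipped = (pb == MISSING_BIN) | (cb == MISSING_BIN)
            term = np.where(skipped, 0.0, term)
            contributed[:, j] = ~skipped
        terms[:, j] = term
    return edges, terms, contributed


# -- persistence ------------------------------------------------------------


def serialize_model(model: PhyloPGMModel) -> str:
    """Serialize a fitted model to a JSON document (full float precision)."""
    doc = {
        "format": _FORMAT_VERSION,
        "tree": model.tree.to_newick(),
        "focal": model.focal,
        "epsilon": model.epsilon,
        "alpha": model.alpha,
        "log_prior_ratio": model.log_prior_ratio,
        "root_marginal": model.root_marginal.tolist(),
        "edges": [
            {"parent": p, "child": c, "table": tbl.tolist()}
            for (p, c), tbl in model.edge_tables.items()
        ],
    }
    return json.dumps(doc)


def deserialize_model(document: str) -> PhyloPGMModel:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format {doc.get('format') if isinstance(doc, dict) else doc!r}"
        )
    try:
        tree = parse_newick(doc["tree"])
        model = PhyloPGMModel(
            tree=tree,
            focal=doc["focal"],
            epsilon=float(doc["epsilon"]),
            alpha=float(doc["alpha"]),
            root_marginal=np.asarray(doc["root_marginal"], dtype=float),
            edge_tables={
                (e["parent"], e["child"]): np.asarray(e["table"], dtype=float)
                for e in doc["edges"]
            },
            log_prior_ratio=float(doc.get("log_prior_ratio", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model document: {exc}") from None
    expected = {(p, c) for p, c, _ in model.tree.edges()}
    if set(model.edge_tables) != expected:
        raise ModelFormatError("edge tables do not match the stored tree")
    return model


# -- hyper-parameter selection (plumbing) -----------------------------------


def select_hyperparameters(
    train: OrthologScoreTable,
    valid: OrthologScoreTable,
    tree: PhyloTree,
    *,
    focal: Optional[str] = None,
    epsilons: Tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    alphas: Tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
) -> Tuple[PhyloPGMModel, Dict[str, float]]:
    """Grid-search (epsilon, alpha) on a validation split by AUPR.

    Refits on the training split only; ties break toward the first grid
    entry.  Returns the winning model and its grid point.
    """
    from .evaluate import aupr  # local import to avoid a module cycle

    if valid.labels is None:
        raise ValueError("validation table must carry labels")
    best = None
    for eps in epsilons:
        for a in alphas:
            model = fit(train, tree, epsilon=eps, alpha=a, focal=focal)
            val_aupr = aupr(scores_array(model, valid), valid.labels.to_numpy())
            if best is None or val_aupr > best[0]:
                best = (val_aupr, model, {"epsilon": eps, "alpha": a})
    assert best is not None
    return best[1], best[2]
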