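"""Synthetic ortholog-score generator.

Emulates the statistical structure the aggregation model assumes: a
binary functional state (bound / not bound) evolves along the rerooted
species tree as a two-state symmetric Markov process -- the state flips
along a branch of length ``e`` with probability ``1 - exp(-mu * e)`` --
and each node's base-predictor score is drawn from a beta distribution
conditioned on that node's state.  The focal (root) state IS the
example's label, so ortholog scores are informative about the label
exactly to the extent that function is conserved.

This produces score tables only; it does not simulate sequences,
motifs, alignments, or correlated binding-site turnover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .score_table import OrthologScoreTable
from .tree import PhyloTree, reroot_at

__all__ = [
    "SimulationConfig",
    "simulate_dataset",
    "simulate_with_states",
    "make_benchmark",
]

FlipProb = Union[float, Mapping[str, float], None]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic ortholog-score generator.

    Attributes
    ----------
    tree:
        species phylogeny; rerooted at ``focal`` internally.
    focal:
        node whose latent state defines the label (default: tree root).
    n_examples:
        number of labeled examples to draw.
    positive_fraction:
        P(label = 1) for each example.
    mu:
        turnover rate per unit branch length; flip probability along a
        branch of length e is 1 - exp(-mu * e).
    emission_pos / emission_neg:
        beta shape pairs (a, b) for scores of nodes in functional /
        non-functional state.  Defaults give means ~0.7 and ~0.3.
    focal_emission_pos / focal_emission_neg:
        optional overrides for the focal species only, used to emulate a
        weaker base predictor on the focal sequence.
    missing_rate:
        per-cell probability that a non-focal score is missing,
        independent of state (missing completely at random).
    flip_prob:
        optional override of the per-branch flip probability: a scalar
        applies to every branch, a mapping {child name: p} to selected
        branches (others keep the mu-based value).  ``flip_prob=0.5``
        makes a branch's child state an independent fair coin, i.e.
        carries no information.
    seed:
        RNG seed; output is deterministic given the seed.
    """

    tree: PhyloTree
    focal: Optional[str] = None
    n_examples: int = 5000
    positive_fraction: float = 0.5
    mu: float = 0.3
    emission_pos: Tuple[float, float] = (3.5, 1.5)
    emission_neg: Tuple[float, float] = (1.5, 3.5)
    focal_emission_pos: Optional[Tuple[float, float]] = None
    focal_emission_neg: Optional[Tuple[float, float]] = None
    missing_rate: float = 0.0
    flip_prob: FlipProb = None
    seed: int = 0


def _branch_flip_probs(tree: PhyloTree, config: SimulationConfig) -> Dict[str, float]:
    if config.mu < 0:
        raise ValueError(f"mu must be >= 0, got {config.mu}")
    probs = {
        child: 1.0 - float(np.exp(-config.mu * length))
        for _parent, child, length in tree.edges()
    }
    if config.flip_prob is not None:
        if isinstance(config.flip_prob, Mapping):
            unknown = set(config.flip_prob) - set(probs)
            if unknown:
                raise ValueError(f"flip_prob overrides for unknown nodes: {sorted(unknown)}")
            probs.update({k: float(v) for k, v in config.flip_prob.items()})
        else:
            probs = {k: float(config.flip_prob) for k in probs}
    for child, p in probs.items():
        if not 0.0 <= p < 1.0:
            raise ValueError(f"flip probability for {child!r} must be in [0, 1), got {p}")
    return probs


def _check_beta(shapes: Tuple[float, float], name: str) -> Tuple[float, float]:
    a, b = shapes
    if a <= 0 or b <= 0:
        raise ValueError(f"{name} beta shapes must be > 0, got {shapes}")
    return float(a), float(b)


def simulate_dataset(config: SimulationConfig) -> OrthologScoreTable:
    """Draw a labeled ortholog score table from the generative model.

    For each example: draw the label Y, set the focal/root latent state
    to Y, propagate states down the rerooted tree with per-branch flip
    probabilities, draw each node's score from the emission distribution
    of its state, then apply missingness to non-focal nodes.
    """
    table, _states = simulate_with_states(config)
    return table


def simulate_with_states(
    config: SimulationConfig,
) -> Tuple[OrthologScoreTable, pd.DataFrame]:
    """Like :func:`simulate_dataset` but also return the latent states.

    The states frame (same index/columns as the score table, values in
    {0, 1}) is the ground truth of the conservation process, useful for
    checking flip frequencies and emission calibration.
    """
    if config.n_examples <= 0:
        raise ValueError("n_examples must be positive")
    if not 0.0 < config.positive_fraction < 1.0:
        raise ValueError("positive_fraction must be in (0, 1)")
    if not 0.0 <= config.missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    emission = {
        1: _check_beta(config.emission_pos, "emission_pos"),
        0: _check_beta(config.emission_neg, "emission_neg"),
    }
    focal_emission = {
        1: _check_beta(config.focal_emission_pos or config.emission_pos, "focal_emission_pos"),
        0: _check_beta(config.focal_emission_neg or config.emission_neg, "focal_emission_neg"),
    }

    focal = config.focal if config.focal is not None else config.tree.root
    tree = reroot_at(config.tree, focal)
    flip = _branch_flip_probs(tree, config)
    order = list(tree.preorder())
    col = {name: i for i, name in enumerate(order)}
    n, m = config.n_examples, len(order)

    rng = np.random.default_rng(config.seed)
    labels = (rng.random(n) < config.positive_fraction).astype(np.int64)

    states = np.empty((n, m), dtype=np.int64)
    states[:, col[focal]] = labels
    for parent, child, _length in tree.edges():
        flips = rng.random(n) < flip[child]
        states[:, col[child]] = states[:, col[parent]] ^ flips.astype(np.int64)

    scores = np.empty((n, m))
    for name in order:
        params = focal_emission if name == focal else emission
        j = col[name]
        for state in (0, 1):
            mask = states[:, j] == state
            a, b = params[state]
            scores[mask, j] = rng.beta(a, b, size=int(mask.sum()))

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        miss[:, col[focal]] = False
        scores[miss] = np.nan

    ids = [f"ex{i:06d}" for i in range(n)]
    index = pd.Index(ids, name="example_id")
    frame = pd.DataFrame(scores, index=index, columns=order)
    states_frame = pd.DataFrame(states, index=index, columns=order)
    table = OrthologScoreTable(frame, pd.Series(labels, index=frame.index))
    return table, states_frame


def make_benchmark(
    config: SimulationConfig,
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> Tuple[OrthologScoreTable, OrthologScoreTable, OrthologScoreTable]:
    """Simulate once and split into (train, validation, test) tables.

    The split is stratified by label (each split's positive fraction is
    within one example of the overall one) and the three id sets are
    disjoint.  Deterministic given ``config.seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    if any(f <= 0 for f in fractions):
        raise ValueError(f"split fractions must be positive, got {fractions}")
    table = simulate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**16 + 1]))
    y = table.labels.to_numpy()
    ids = np.asarray(table.example_ids)

    parts: list[list[str]] = [[], [], []]
    for cls in (0, 1):
        members = ids[y == cls]
        members = members[rng.permutation(len(members))]
        n = len(members)
        n_train = int(round(fractions[0] * n))
        n_valid = int(round(fractions[1] * n))
        parts[0].extend(members[:n_train])
        parts[1].extend(members[n_train : n_train + n_valid])
        parts[2].extend(members[n_train + n_valid :])
    # keep original row order within each split
    position = {eid: i for i, eid in enumerate(ids)}
    train, valid, test = (sorted(p, key=position.__getitem__) for p in parts)
    return table.subset(train), table.subset(valid), table.subset(test)
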