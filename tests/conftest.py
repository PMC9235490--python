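"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (breadth-first
path sums, exhaustive threshold scans, brute-force factorized joints)
so they stay independent of the library code paths they check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pytest

from phylopgm.score_table import OrthologScoreTable
from phylopgm.tree import PhyloTree, parse_newick


# -- table construction ------------------------------------------------------


def make_table(
    columns: Sequence[str],
    rows: Sequence[Sequence[Optional[float]]],
    labels: Optional[Sequence[int]] = None,
    ids: Optional[Sequence[str]] = None,
) -> OrthologScoreTable:
    """Build a score table from literal rows; None entries are missing."""
    ids = list(ids) if ids is not None else [f"e{i}" for i in range(len(rows))]
    data = [[np.nan if v is None else float(v) for v in row] for row in rows]
    frame = pd.DataFrame(
        data, index=pd.Index(ids, name="example_id"), columns=list(columns)
    )
    lab = pd.Series(list(labels), index=frame.index) if labels is not None else None
    return OrthologScoreTable(frame, lab)


# -- independent path-length oracle -----------------------------------------


def bf_path_lengths(
    tree: PhyloTree, nodes: Optional[Sequence[str]] = None
) -> Dict[frozenset, float]:
    """All-pairs path lengths via breadth-first traversal of the edges.

    ``nodes`` defaults to the tree's leaves; pass an explicit list when
    comparing trees whose leaf sets differ formally (a focal leaf made
    root has degree 1 and is no longer counted as a leaf).
    """
    adjacency: Dict[str, List[Tuple[str, float]]] = {}
    for parent, child, length in tree.edges():
        adjacency.setdefault(parent, []).append((child, length))
        adjacency.setdefault(child, []).append((parent, length))
    leaves = list(nodes) if nodes is not None else tree.leaf_names
    out: Dict[frozenset, float] = {}
    for source in leaves:
        dist = {source: 0.0}
        frontier = [source]
        while frontier:
            node = frontier.pop()
            for nbr, length in adjacency.get(node, ()):
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    frontier.append(nbr)
        for target in leaves:
            out[frozenset((source, target))] = dist[target]
    return out


# -- random tree generator ---------------------------------------------------


def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random binary topology with random branch lengths in (0, 1]."""
    children: Dict[str, List[str]] = {}
    blen: Dict[str, float] = {}
    subtrees = [f"L{i}" for i in range(n_leaves)]
    counter = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        name = f"I{counter}"
        counter += 1
        children[name] = [a, b]
        blen[a] = float(rng.uniform(0.01, 1.0))
        blen[b] = float(rng.uniform(0.01, 1.0))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(name)
    return PhyloTree(subtrees[0], children, blen)


def random_table(
    rng: np.random.Generator,
    tree: PhyloTree,
    n_examples: int,
    missing_rate: float = 0.1,
) -> OrthologScoreTable:
    """Random labeled table over all tree nodes, with some missing cells."""
    nodes = list(tree.preorder())
    scores = rng.random((n_examples, len(nodes)))
    miss = rng.random((n_examples, len(nodes))) < missing_rate
    scores[miss] = np.nan
    frame = pd.DataFrame(
        scores,
        index=pd.Index([f"r{i}" for i in range(n_examples)], name="example_id"),
        columns=nodes,
    )
    labels = pd.Series(rng.integers(0, 2, size=n_examples), index=frame.index)
    return OrthologScoreTable(frame, labels)


# -- exhaustive ranking-metric oracles ---------------------------------------


def bf_average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise AUPR by scanning the top-k prefixes of the ranking.

    Assumes distinct scores (no tie handling needed).
    """
    order = np.argsort(scores)[::-1]
    y = np.asarray(labels)[order]
    total_pos = int(y.sum())
    area, prev_recall = 0.0, 0.0
    tp = 0
    for k in range(len(y)):
        tp += int(y[k])
        precision = tp / (k + 1)
        recall = tp / total_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def bf_recall_at_fdr(
    scores: Sequence[float], labels: Sequence[int], fdr: float
) -> float:
    """Best recall over all top-k cutoffs with empirical FDR <= fdr."""
    order = np.argsort(scores)[::-1]
    y = np.asarray(labels)[order]
    total_pos = int(y.sum())
    best = 0.0
    tp = 0
    for k in range(len(y)):
        tp += int(y[k])
        precision = tp / (k + 1)
        if 1.0 - precision <= fdr:
            best = max(best, tp / total_pos)
    return best


# -- fixtures ----------------------------------------------------------------


@pytest.fixture
def five_node_tree() -> PhyloTree:
    return parse_newick("((A:1.0,B:2.0)N1:0.5,C:3.0)R;")


@pytest.fixture
def chain_tree() -> PhyloTree:
    """Root A with single descendant B: one edge, the minimal fit target."""
    return parse_newick("(B:1.0)A;")


@pytest.fixture
def cherry_tree() -> PhyloTree:
    """Root A with two children: the 3-node tree of the scoring oracle."""
    return parse_newick("(B:0.5,C:0.7)A;")
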