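"""Fitting the probability tables and computing the aggregation score."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from phylopgm.model import (
    ModelFormatError,
    deserialize_model,
    edge_llr_terms,
    fit,
    score_example,
    score_table,
    scores_array,
    select_hyperparameters,
    serialize_model,
)
from phylopgm.score_table import MISSING_BIN, N_BINS, OrthologScoreTable
from phylopgm.tree import parse_newick

from .conftest import make_table, random_table, random_tree


def bf_factorized_llr(model, bins_by_node: dict) -> float:
    """Independent brute-force evaluation of log P[s|Y=1]/P[s|Y=0].

    Multiplies the root marginal and every edge conditional directly
    from the fitted tables (uniform class prior cancels).
    """
    logp = {}
    order = {name: i for i, name in enumerate(model.node_order)}
    for y in (0, 1):
        p = np.log(model.root_marginal[y, bins_by_node[model.focal]])
        for (parent, child), tbl in model.edge_tables.items():
            p += np.log(tbl[y, bins_by_node[parent], bins_by_node[child]])
        logp[y] = p
    assert set(bins_by_node) == set(order)
    return logp[1] - logp[0]


class TestFitFormulas:
    def test_empty_training_set_gives_uniform_tables(self, chain_tree):
        empty = make_table(["A", "B"], [], labels=[])
        with pytest.warns(UserWarning, match="empty"):
            m = fit(empty, chain_tree, epsilon=1.0)
        np.testing.assert_allclose(m.root_marginal, 1.0 / 12)
        for tbl in m.edge_tables.values():
            np.testing.assert_allclose(tbl, 1.0 / 12)

    def test_single_positive_focal_score_counts(self, chain_tree):
        # one positive with focal score 0.7 (bin 7): P[bin7|Y=1]=(1+1)/(1+12)
        train = make_table(["A", "B"], [[0.7, 0.2]], labels=[1])
        m = fit(train, chain_tree, epsilon=1.0)
        assert m.root_marginal[1, 7] == pytest.approx(2 / 13, rel=1e-15)
        assert m.root_marginal[1, 3] == pytest.approx(1 / 13, rel=1e-15)
        # no negatives seen: the Y=0 side is pseudocount-only
        np.testing.assert_allclose(m.root_marginal[0], 1.0 / 12)

    def test_edge_conditional_counts(self, chain_tree):
        # two positives with parent bin 5 and child bins 5, 6:
        # P[5|5,Y=1] = (1+1)/(2+12)
        train = make_table(["A", "B"], [[0.5, 0.5], [0.5, 0.6]], labels=[1, 1])
        m = fit(train, chain_tree, epsilon=1.0)
        tbl = m.edge_tables[("A", "B")]
        assert tbl[1, 5, 5] == pytest.approx(2 / 14, rel=1e-15)
        assert tbl[1, 5, 6] == pytest.approx(2 / 14, rel=1e-15)
        assert tbl[1, 5, 0] == pytest.approx(1 / 14, rel=1e-15)
        assert tbl[1, 4, 4] == pytest.approx(1 / 12, rel=1e-15)

    def test_missing_scores_fill_the_missing_bin_at_fit_time(self, chain_tree):
        train = make_table(["A", "B"], [[0.5, None]], labels=[1])
        m = fit(train, chain_tree, epsilon=1.0)
        # one parent-bin-5 positive example: (1+1)/(1+12)
        assert m.edge_tables[("A", "B")][1, 5, MISSING_BIN] == pytest.approx(2 / 13)

    def test_epsilon_must_be_positive(self, chain_tree):
        train = make_table(["A", "B"], [[0.5, 0.5]], labels=[1])
        with pytest.raises(ValueError, match="epsilon"):
            fit(train, chain_tree, epsilon=0.0)

    def test_labels_required(self, chain_tree):
        with pytest.raises(ValueError, match="labels"):
            fit(make_table(["A", "B"], [[0.5, 0.5]]), chain_tree)

    @pytest.mark.parametrize("seed", range(5))
    def test_fitted_distributions_are_normalized_and_positive(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, int(rng.integers(3, 8)))
        tree_rooted = tree
        train = random_table(rng, tree_rooted, 25, missing_rate=0.2)
        m = fit(train, tree_rooted, epsilon=float(rng.choice([0.01, 0.1, 1, 10])))
        np.testing.assert_allclose(m.root_marginal.sum(axis=1), 1.0, atol=1e-9)
        assert (m.root_marginal > 0).all()
        for tbl in m.edge_tables.values():
            np.testing.assert_allclose(tbl.sum(axis=2), 1.0, atol=1e-9)
            assert (tbl > 0).all()


class TestScoring:
    @pytest.fixture
    def cherry_model(self, cherry_tree):
        rng = np.random.default_rng(42)
        train = random_table(rng, cherry_tree, 60, missing_rate=0.15)
        return fit(train, cherry_tree, epsilon=1.0, alpha=1.0)

    def test_matches_bruteforce_on_complete_assignments(self, cherry_model):
        # spot-check a sample here; the exhaustive 12^3 sweep runs in the
        # acceptance suite
        rng = np.random.default_rng(0)
        nodes = cherry_model.node_order
        for _ in range(50):
            bins = {n: int(rng.integers(0, N_BINS)) for n in nodes}
            row = [None if bins[n] == MISSING_BIN else bins[n] / 10 for n in nodes]
            table = make_table(nodes, [row])
            got = score_example(cherry_model, table, missing="bin")
            assert got.phylopgm_score == pytest.approx(
                bf_factorized_llr(cherry_model, bins), abs=1e-9
            )

    def test_alpha_zero_reduces_to_root_llr(self, cherry_tree):
        rng = np.random.default_rng(1)
        train = random_table(rng, cherry_tree, 40)
        m = fit(train, cherry_tree, epsilon=1.0, alpha=0.0)
        test = random_table(rng, cherry_tree, 20)
        for r in score_table(m, test):
            assert r.phylopgm_score == pytest.approx(r.root_llr, abs=1e-12)

    def test_all_orthologs_missing_leaves_root_llr(self, cherry_model):
        table = make_table(cherry_model.node_order, [[0.8, None, None]])
        r = score_example(cherry_model, table)
        assert r.branch_llr_sum == 0.0
        assert r.phylopgm_score == pytest.approx(r.root_llr, abs=1e-12)

    def test_missing_focal_skips_root_term(self, cherry_model):
        table = make_table(cherry_model.node_order, [[None, 0.4, 0.6]])
        r = score_example(cherry_model, table)
        assert r.root_llr == 0.0
        assert r.phylopgm_score == pytest.approx(
            cherry_model.alpha * r.branch_llr_sum, abs=1e-12
        )

    def test_uniform_model_scores_zero_and_predicts_negative(self, cherry_tree):
        empty = make_table(list(cherry_tree.preorder()), [], labels=[])
        with pytest.warns(UserWarning):
            m = fit(empty, cherry_tree, epsilon=1.0, alpha=1.0)
        rng = np.random.default_rng(2)
        test = random_table(rng, cherry_tree, 10)
        for r in score_table(m, test):
            assert r.phylopgm_score == 0.0
            assert r.predicted_label == 0  # exact zero is not > 0

    def test_score_decomposition_invariant(self, cherry_model):
        rng = np.random.default_rng(3)
        test = random_table(rng, cherry_model.tree, 30, missing_rate=0.2)
        for r in score_table(cherry_model, test):
            assert r.phylopgm_score == pytest.approx(
                r.root_llr + cherry_model.alpha * r.branch_llr_sum, abs=1e-9
            )
            assert r.predicted_label == int(r.phylopgm_score > 0)

    def test_label_swap_negates_scores(self, cherry_tree):
        rng = np.random.default_rng(4)
        train = random_table(rng, cherry_tree, 50, missing_rate=0.1)
        swapped = OrthologScoreTable(train.scores.copy(), 1 - train.labels)
        test = random_table(rng, cherry_tree, 25, missing_rate=0.1)
        s = scores_array(fit(train, cherry_tree, alpha=0.7), test)
        s_swapped = scores_array(fit(swapped, cherry_tree, alpha=0.7), test)
        np.testing.assert_allclose(s_swapped, -s, atol=1e-9)

    def test_all_missing_species_is_inert(self):
        """A species missing everywhere changes no score vs. a tree without it."""
        base = parse_newick("(B:0.5,C:0.7)A;")
        extended = parse_newick("(B:0.5,C:0.7,D:0.3)A;")
        rng = np.random.default_rng(5)
        train = random_table(rng, base, 40)
        test = random_table(rng, base, 20)
        m_base = fit(train, base, alpha=1.0)
        m_ext = fit(train, extended, alpha=1.0)  # D has no column -> all missing
        np.testing.assert_allclose(
            scores_array(m_ext, test), scores_array(m_base, test), atol=1e-12
        )

    def test_scores_shrink_to_zero_as_epsilon_grows(self, cherry_tree):
        rng = np.random.default_rng(6)
        train = random_table(rng, cherry_tree, 50)
        test = random_table(rng, cherry_tree, 20)
        magnitudes = [
            np.abs(scores_array(fit(train, cherry_tree, epsilon=e, alpha=1.0), test)).max()
            for e in (1.0, 1e3, 1e9)
        ]
        assert magnitudes[0] > magnitudes[1] > magnitudes[2]
        assert magnitudes[2] < 1e-3

    def test_score_example_requires_single_row(self, cherry_model):
        two = make_table(cherry_model.node_order, [[0.1] * 3, [0.2] * 3])
        with pytest.raises(ValueError, match="1 example"):
            score_example(cherry_model, two)

    def test_edge_terms_mark_skipped_contributions(self, cherry_model):
        table = make_table(cherry_model.node_order, [[0.8, None, 0.6]])
        edges, terms, contributed = edge_llr_terms(cherry_model, table)
        j_missing = edges.index(("A", "B"))
        assert not contributed[0, j_missing]
        assert terms[0, j_missing] == 0.0


class TestPersistence:
    def test_roundtrip_scores_identically(self, cherry_tree):
        rng = np.random.default_rng(7)
        train = random_table(rng, cherry_tree, 30)
        test = random_table(rng, cherry_tree, 15, missing_rate=0.2)
        m = fit(train, cherry_tree, epsilon=0.5, alpha=0.3)
        m2 = deserialize_model(serialize_model(m))
        np.testing.assert_allclose(
            scores_array(m2, test), scores_array(m, test), atol=1e-12
        )
        assert m2.epsilon == m.epsilon and m2.alpha == m.alpha
        assert m2.focal == m.focal

    def test_truncated_document_raises(self, cherry_tree):
        rng = np.random.default_rng(8)
        m = fit(random_table(rng, cherry_tree, 10), cherry_tree)
        doc = serialize_model(m)
        with pytest.raises(ModelFormatError):
            deserialize_model(doc[: len(doc) // 2])

    def test_wrong_format_tag_raises(self):
        with pytest.raises(ModelFormatError, match="format"):
            deserialize_model(json.dumps({"format": "something-else"}))

    def test_edge_table_count_matches_tree(self, five_node_tree):
        rng = np.random.default_rng(9)
        m = fit(random_table(rng, five_node_tree, 10), five_node_tree)
        doc = json.loads(serialize_model(m))
        assert len(doc["edges"]) == 4


class TestHyperparameterSearch:
    def test_returns_grid_member_maximizing_validation_aupr(self, cherry_tree):
        rng = np.random.default_rng(10)
        train = random_table(rng, cherry_tree, 60)
        valid = random_table(rng, cherry_tree, 40)
        model, hp = select_hyperparameters(
            train, valid, cherry_tree, epsilons=(0.1, 1.0), alphas=(0.1, 1.0)
        )
        assert hp["epsilon"] in (0.1, 1.0) and hp["alpha"] in (0.1, 1.0)
        assert model.epsilon == hp["epsilon"] and model.alpha == hp["alpha"]
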