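"""Parsimony scoring: Sankoff DP vs exhaustive enumeration and an
independent Fitch implementation, min/max step extremes, ensemble indices
and unambiguous-synapomorphy detection."""

import dendropy
import numpy as np
import pytest
from dendropy.model.parsimony import fitch_down_pass

from conftest import as_package_tree
from oracles import all_rooted_binary_topologies, brute_force_char_length
from stratofit import (CharacterMatrix, SimulationConfig, character_length,
                       char_max_steps, char_min_steps, parse_newick,
                       simulate_characters, simulate_tree, tree_fit_indices,
                       tree_length, unambiguous_synapomorphies, write_newick,
                       write_nexus)


def random_instance(rng, n_tips, n_states, ordered):
    """Random tree + single-character matrix with missing/polymorphic cells."""
    labels = [f"T{i}" for i in range(n_tips)]
    topos = all_rooted_binary_topologies(labels)
    tree_tuples = topos[int(rng.integers(len(topos)))]
    cells = {}
    for t in labels:
        u = rng.random()
        if u < 0.15:
            cells[t] = None  # missing
        elif u < 0.3:
            size = int(rng.integers(2, n_states + 1))
            cells[t] = set(rng.choice(n_states, size=size, replace=False).tolist())
        else:
            cells[t] = {int(rng.integers(n_states))}
    symbols = []
    for t in labels:
        cell = cells[t]
        if cell is None:
            symbols.append("?")
        elif len(cell) == 1:
            symbols.append(str(next(iter(cell))))
        else:
            symbols.append("{" + "".join(map(str, sorted(cell))) + "}")
    matrix = CharacterMatrix.from_symbols(labels, symbols,
                                          ordered=[1] if ordered else [])
    return tree_tuples, cells, matrix


class TestCharacterLength:
    def test_small_tree_worked_examples(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["0", "1", "0", "1"])
        assert character_length(t, m, 1) == 2
        cherry = parse_newick("(A,B);")
        m02 = CharacterMatrix.from_symbols(["A", "B"], ["0", "2"])
        assert character_length(cherry, m02, 1) == 1
        assert character_length(cherry, m02.with_ordered([1]), 1) == 2
        star = parse_newick("(A,B,C,D);")
        m2 = CharacterMatrix.from_symbols(list("ABCD"), ["0", "0", "1", "2"])
        assert character_length(star, m2, 1) == 2

    @pytest.mark.parametrize("ordered", [False, True])
    def test_dp_matches_exhaustive_enumeration(self, ordered):
        rng = np.random.default_rng(5 + ordered)
        for _ in range(300):
            n_tips = int(rng.integers(3, 7))
            n_states = int(rng.integers(2, 5))
            tree_tuples, cells, matrix = random_instance(
                rng, n_tips, n_states, ordered)
            got = character_length(as_package_tree(tree_tuples), matrix, 1)
            want = brute_force_char_length(tree_tuples, cells, ordered, n_states)
            assert got == pytest.approx(want), (tree_tuples, cells, ordered)

    def test_matches_independent_fitch_implementation(self):
        # unordered characters on binary trees vs dendropy's Fitch pass
        for seed in range(15):
            config = SimulationConfig(n_tips=10, seed=seed, n_characters=25,
                                      n_states=3, change_rate=4.0,
                                      missing_prob=0.1, polymorphism_prob=0.05)
            tree = simulate_tree(config)
            matrix = simulate_characters(tree, config)
            ds = dendropy.DataSet.get(
                data=write_nexus(matrix) +
                f"BEGIN TREES;\nTREE t = {write_newick(tree)}\nEND;\n",
                schema="nexus")
            tsm = ds.char_matrices[0].taxon_state_sets_map(gaps_as_missing=True)
            score = fitch_down_pass(ds.tree_lists[0][0].postorder_node_iter(),
                                    taxon_state_sets_map=tsm)
            assert tree_length(tree, matrix) == score

    def test_ordered_never_shorter_than_unordered(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            tree_tuples, _, matrix = random_instance(rng, 6, 4, ordered=False)
            tree = as_package_tree(tree_tuples)
            s_u = character_length(tree, matrix, 1)
            s_o = character_length(tree, matrix.with_ordered([1]), 1)
            assert s_o >= s_u

    def test_collapsing_edge_never_decreases_steps(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            tree_tuples, _, matrix = random_instance(rng, 6, 3, ordered=False)
            tree = as_package_tree(tree_tuples)
            s = character_length(tree, matrix, 1)
            internal = [n for n in tree.internal_nodes() if n.parent is not None]
            for node in internal:
                collapsed = tree.copy()
                target = next(n for n in collapsed.postorder()
                              if not n.is_leaf and n.tip_labels() == node.tip_labels()
                              and n.parent is not None)
                parent = target.parent
                parent.children = [c for c in parent.children if c is not target]
                for child in target.children:
                    parent.add_child(child)
                assert character_length(collapsed, matrix, 1) >= s

    def test_all_missing_character_is_free(self):
        t = parse_newick("((A,B),C);")
        m = CharacterMatrix.from_symbols(list("ABC"), ["?", "?", "-"])
        assert character_length(t, m, 1) == 0

    def test_tree_length_additive(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"),
                                         ["00", "10", "01", "11"])
        assert tree_length(t, m) == 3
        const = CharacterMatrix.from_symbols(list("ABCD"), ["0"] * 4)
        assert tree_length(t, const) == 0

    def test_simulated_true_changes_bound_parsimony_length(self):
        for seed in range(10):
            config = SimulationConfig(n_tips=10, seed=seed, n_characters=40,
                                      change_rate=3.0)
            tree = simulate_tree(config)
            matrix = simulate_characters(tree, config)
            for c in range(1, matrix.n_characters + 1):
                assert character_length(tree, matrix, c) <= \
                    matrix.true_changes[c - 1]


class TestMinMaxSteps:
    def test_min_examples(self):
        m = CharacterMatrix.from_symbols(list("ABC"), ["0", "1", "2"])
        assert char_min_steps(m, 1) == 2
        poly = CharacterMatrix.from_symbols(list("AB"), ["0", "{01}"])
        assert char_min_steps(poly, 1) == 0
        far = CharacterMatrix.from_symbols(list("AB"), ["0", "3"]).with_ordered([1])
        assert char_min_steps(far, 1) == 3

    def test_max_examples(self):
        m = CharacterMatrix.from_symbols(list("ABCDEF"),
                                         ["0", "0", "0", "1", "1", "2"])
        assert char_max_steps(m, 1) == 3
        om = CharacterMatrix.from_symbols(list("ABC"),
                                          ["0", "1", "3"]).with_ordered([1])
        assert char_max_steps(om, 1) == 3
        const = CharacterMatrix.from_symbols(list("ABC"), ["1", "1", "1"])
        assert char_max_steps(const, 1) == 0

    def test_m_le_s_le_g_random(self):
        rng = np.random.default_rng(21)
        for ordered in (False, True):
            for _ in range(100):
                tree_tuples, _, matrix = random_instance(rng, 6, 4, ordered)
                tree = as_package_tree(tree_tuples)
                m = char_min_steps(matrix, 1)
                s = character_length(tree, matrix, 1)
                g = char_max_steps(matrix, 1)
                assert m <= s + 1e-9 and s <= g + 1e-9


class TestEnsembleIndices:
    def test_toy_ensemble(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["00", "10", "01", "11"])
        stats = tree_fit_indices(t, m)
        assert stats.length == 3
        assert stats.CI == pytest.approx(2 / 3)
        assert stats.RI == pytest.approx(0.5)
        assert stats.HI == pytest.approx(1 / 3)
        assert stats.RC == pytest.approx(1 / 3)

    def test_clean_matrix_perfect_indices(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["0", "0", "1", "1"])
        stats = tree_fit_indices(t, m)
        assert (stats.CI, stats.RI, stats.HI) == (1.0, 1.0, 0.0)

    def test_maximally_homoplastic_ri_zero(self):
        t = parse_newick("((A,C),(B,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["0", "0", "1", "1"])
        stats = tree_fit_indices(t, m)
        assert stats.per_character[0].ri == 0.0

    def test_uninformative_exclusion_changes_ci_only(self):
        t = parse_newick("((A,B),(C,D));")
        # char 2 is an autapomorphy: g == m == 1, uninformative
        m = CharacterMatrix.from_symbols(list("ABCD"),
                                         ["00", "10", "01", "10"])
        incl = tree_fit_indices(t, m)
        excl = tree_fit_indices(t, m, exclude_uninformative=True)
        assert not incl.per_character[1].informative
        assert excl.CI < incl.CI  # dropping a clean character lowers CI
        assert excl.RI == incl.RI

    def test_reported_length_substitution(self):
        t = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["00", "10", "01", "11"])
        stats = tree_fit_indices(t, m, reported_length=4.0)
        assert stats.length == 4.0
        assert stats.CI == pytest.approx(2 / 4)


class TestSynapomorphies:
    def test_outgroup_anchored_change_is_unambiguous(self):
        tree = parse_newick("(O,((A,B),(C,D)));")
        m = CharacterMatrix.from_symbols(list("OABCD"),
                                         ["0", "0", "0", "1", "1"])
        node = tree.mrca(["C", "D"])
        hits = unambiguous_synapomorphies(tree, m, node)
        assert [(h.char_index, h.derived_state) for h in hits] == [(1, 1)]

    def test_rootstate_ambiguity_without_outgroup(self):
        # on a 4-taxon tree the root state itself is ambiguous, so the
        # change can sit on either root branch: not unambiguous
        tree = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["0", "0", "1", "1"])
        assert unambiguous_synapomorphies(tree, m, tree.mrca(["C", "D"])) == []

    def test_homoplastic_character_is_ambiguous(self):
        tree = parse_newick("(O,((A,B),(C,D)));")
        m = CharacterMatrix.from_symbols(list("OABCD"),
                                         ["0", "0", "1", "0", "1"])
        assert unambiguous_synapomorphies(tree, m, tree.mrca(["C", "D"])) == []

    def test_constant_character_never_flagged(self):
        tree = parse_newick("(O,((A,B),(C,D)));")
        m = CharacterMatrix.from_symbols(list("OABCD"), ["1"] * 5)
        for node in tree.internal_nodes():
            if node.parent is not None:
                assert unambiguous_synapomorphies(tree, m, node) == []

    def test_agrees_with_optimal_labeling_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            tree_tuples, cells, matrix = random_instance(rng, 5, 3, False)
            tree = as_package_tree(tree_tuples)
            opt = character_length(tree, matrix, 1)
            for node in tree.internal_nodes():
                if node.parent is None:
                    continue
                hits = unambiguous_synapomorphies(tree, matrix, node)
                flagged = bool(hits)
                # enumeration: is there an optimal labeling with no change
                # on the branch subtending `node`?
                change_free = _min_cost_with_equal_branch(tree, matrix, node)
                assert flagged == (change_free > opt + 1e-9), \
                    (tree_tuples, cells, node.tip_labels())

    def test_root_has_no_subtending_branch(self):
        tree = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix.from_symbols(list("ABCD"), ["0", "0", "1", "1"])
        with pytest.raises(ValueError):
            unambiguous_synapomorphies(tree, m, tree.root)


def _min_cost_with_equal_branch(tree, matrix, node):
    """Brute force: minimum cost over all internal labelings in which the
    branch above *node* carries no change (independent of the DP)."""
    from itertools import product as iproduct

    states = sorted(matrix.universe(1))
    internals = tree.internal_nodes()
    tax = {t: i for i, t in enumerate(matrix.taxa)}
    best = float("inf")
    for assign in iproduct(states, repeat=len(internals)):
        label = dict(zip(map(id, internals), assign))

        def state_of(n):
            if n.is_leaf:
                return None
            return label[id(n)]

        parent_state = state_of(node.parent)
        node_state = state_of(node) if not node.is_leaf else None
        if node.is_leaf:
            cell = matrix.cells[tax[node.label]][0]
            if matrix.is_missing(tax[node.label], 1) or parent_state in cell:
                node_ok = True
            else:
                node_ok = False
            if not node_ok:
                continue
        elif node_state != parent_state:
            continue
        cost = 0.0
        for n in tree.postorder():
            for child in n.children:
                ps = state_of(n)
                if child.is_leaf:
                    i = tax[child.label]
                    if matrix.is_missing(i, 1):
                        continue
                    cell = matrix.cells[i][0]
                    if child is node:
                        cost += 0 if ps in cell else float("inf")
                    else:
                        cost += 0 if ps in cell else 1
                else:
                    cost += 0 if ps == state_of(child) else 1
        best = min(best, cost)
    return best
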