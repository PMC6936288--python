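"""Independent brute-force oracles used by the test suite.

Everything here works on plain nested tuples (a tree is either a taxon
label string or a tuple of subtrees), deliberately sharing no code with the
package under test.
"""

from __future__ import annotations

from itertools import product

import numpy as np

# ---------------------------------------------------------------------------
# topology enumeration


def all_rooted_binary_topologies(labels):
    """Every rooted binary topology on *labels* as nested tuples:
    (2n-3)!! trees, built by inserting each new leaf into every edge
    (including above the root) of every smaller tree."""
    labels = list(labels)
    trees = [labels[0]]
    for leaf in labels[1:]:
        nxt = []
        for tree in trees:
            nxt.extend(_insert_everywhere(tree, leaf))
        trees = nxt
    return trees


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)  # above the current root
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insert_everywhere(left, leaf):
            yield (sub, right)
        for sub in _insert_everywhere(right, leaf):
            yield (left, sub)


def all_resolutions(children):
    """All rooted binary trees whose leaves are the given child subtrees
    (used to brute-force polytomy resolutions)."""
    if len(children) == 1:
        return [children[0]]
    return [_map_leaves(tree, children)
            for tree in all_rooted_binary_topologies(list(range(len(children))))]


def _map_leaves(tree, children):
    if isinstance(tree, tuple):
        return tuple(_map_leaves(t, children) for t in tree)
    return children[tree]


def tips_of(tree):
    if isinstance(tree, tuple):
        out = []
        for sub in tree:
            out.extend(tips_of(sub))
        return out
    return [tree]


# ---------------------------------------------------------------------------
# ghost lineages


def mig_of(tree, fads):
    """Minimum implied gap of a nested-tuple tree under a FAD dict,
    computed by direct recursion (hard polytomies)."""

    def age(node):
        if isinstance(node, tuple):
            return max(age(c) for c in node)
        return fads[node]

    def gaps(node):
        if not isinstance(node, tuple):
            return 0.0
        a = age(node)
        return sum((a - age(c)) + gaps(c) for c in node)

    return gaps(tree)


def brute_force_gmin(labels, fads):
    """Minimum MIG over every rooted binary topology."""
    return min(mig_of(t, fads) for t in all_rooted_binary_topologies(labels))


def pectinate(labels_sorted):
    """Ladder tree, first label outermost."""
    tree = (labels_sorted[-2], labels_sorted[-1])
    for label in reversed(labels_sorted[:-2]):
        tree = (label, tree)
    return tree


# ---------------------------------------------------------------------------
# parsimony


def brute_force_char_length(tree, cells, ordered, n_states):
    """Exact minimum steps by exhaustive enumeration over all internal-node
    state assignments (tips choose their best state given the parent).

    *cells* maps taxon -> set of allowed states, or None for missing.
    """
    idx = np.arange(n_states)
    if ordered:
        step = np.abs(idx[:, None] - idx[None, :]).astype(float)
    else:
        step = (idx[:, None] != idx[None, :]).astype(float)

    internals, internal_edges, tip_entries = [], [], []

    def walk(node):
        """Returns index of the node in *internals* (internal) or None."""
        if not isinstance(node, tuple):
            return None
        me = len(internals)
        internals.append(node)
        for child in node:
            ci = walk(child)
            if ci is None:
                tip_entries.append((me, child))
            else:
                internal_edges.append((me, ci))
        return me

    walk(tree)
    n_int = len(internals)
    grids = np.array(list(product(range(n_states), repeat=n_int)))
    cost = np.zeros(len(grids))
    for p, c in internal_edges:
        cost += step[grids[:, p], grids[:, c]]
    for p, taxon in tip_entries:
        cell = cells[taxon]
        if cell is None:  # missing: free
            continue
        tip_cost = np.min(step[:, sorted(cell)], axis=1)
        cost += tip_cost[grids[:, p]]
    return float(cost.min())
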