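"""Parsimony scoring of trees against discrete character matrices.

Character lengths are computed by generalized (Sankoff) dynamic programming
over the rooted tree: each node carries a cost vector over states, a tip
costs 0 for any state in its state set and infinity otherwise (polymorphism
is scored any-of; missing data costs 0 everywhere), and an internal node's
cost for state ``s`` sums, over children, the minimum of child cost plus
the step cost.  Step costs are unit for unordered (Fitch) characters and
``|i - j|`` for ordered (Wagner) characters; polytomies are handled
natively by the same recursion.

Per-character extremes use the standard symbols:

* ``m`` — minimum conceivable steps on any tree,
* ``s`` — steps on the given tree,
* ``g`` — steps on the completely unresolved star tree (the maximum),

from which the ensemble indices follow: CI = Σm/Σs, RI = (Σg−Σs)/(Σg−Σm),
HI = 1 − CI, RC = CI × RI.  Characters with g == m cannot show homoplasy
and are flagged uninformative; they are excluded from the RI sums, and a
flag recomputes CI/HI without them (both reporting conventions exist in
common use and are mutually inconsistent, so both are exposed).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np

from .characters import CharacterMatrix
from .tree import Node, Tree

__all__ = [
    "CharacterFit", "TreeFitStats", "Synapomorphy",
    "character_length", "tree_length", "char_min_steps", "char_max_steps",
    "tree_fit_indices", "unambiguous_synapomorphies",
]

_INF = float("inf")


def _step_cost(ordered: bool, n_states: int) -> np.ndarray:
    idx = np.arange(n_states)
    if ordered:
        return np.abs(idx[:, None] - idx[None, :]).astype(float)
    return (idx[:, None] != idx[None, :]).astype(float)


def _state_space(matrix: CharacterMatrix, char: int) -> list[int]:
    """States the DP ranges over: observed states for unordered characters,
    the full integer range min..max for ordered ones (optimal internal
    states may be intermediate)."""
    universe = matrix.universe(char)
    if matrix.is_ordered(char) and len(universe) > 1:
        return list(range(min(universe), max(universe) + 1))
    return sorted(universe)


def _tip_costs(cell: frozenset[int], missing: bool,
               states: list[int]) -> np.ndarray:
    if missing:
        return np.zeros(len(states))
    costs = np.full(len(states), _INF)
    for k, s in enumerate(states):
        if s in cell:
            costs[k] = 0.0
    return costs


def _down_pass(tree: Tree, matrix: CharacterMatrix, char: int
               ) -> tuple[dict[Node, np.ndarray], np.ndarray, list[int]]:
    """Sankoff down-pass: per-node cost vectors, step-cost matrix, states."""
    states = _state_space(matrix, char)
    step = _step_cost(matrix.is_ordered(char), len(states))
    tax_index = {t: i for i, t in enumerate(matrix.taxa)}
    down: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            i = tax_index[node.label]
            down[node] = _tip_costs(matrix.cells[i][char - 1],
                                    matrix.is_missing(i, char), states)
        else:
            total = np.zeros(len(states))
            for child in node.children:
                total += np.min(down[child][None, :] + step, axis=1)
            down[node] = total
    return down, step, states


def character_length(tree: Tree, matrix: CharacterMatrix, char: int) -> float:
    """Minimum total steps for one character (1-based index) on the tree."""
    down, _, _ = _down_pass(tree, matrix, char)
    return float(np.min(down[tree.root]))


def tree_length(tree: Tree, matrix: CharacterMatrix) -> float:
    """Total parsimony length: sum of character lengths over all characters."""
    return sum(character_length(tree, matrix, c)
               for c in range(1, matrix.n_characters + 1))


def char_min_steps(matrix: CharacterMatrix, char: int) -> float:
    """Minimum conceivable steps ``m`` for a character on any tree.

    Each scored cell may be satisfied by any of its states (any-of
    polymorphism); representatives are chosen to minimize the result.
    Unordered: (size of the smallest state set hitting every cell) − 1.
    Ordered: the width of the narrowest state interval hitting every cell.
    """
    cells = matrix.scored_column(char)
    if not cells:
        return 0.0
    observed = sorted({s for cell in cells for s in cell})
    if matrix.is_ordered(char):
        best = _INF
        for lo in observed:
            for hi in observed:
                if lo <= hi and all(any(lo <= s <= hi for s in cell)
                                    for cell in cells):
                    best = min(best, hi - lo)
        return float(best)
    # unordered: smallest hitting set of the cells' state sets
    for size in range(1, len(observed) + 1):
        for combo in combinations(observed, size):
            chosen = set(combo)
            if all(cell & chosen for cell in cells):
                return float(size - 1)
    return float(len(observed) - 1)  # unreachable


def char_max_steps(matrix: CharacterMatrix, char: int) -> float:
    """Steps ``g`` on the star tree (single internal node): the exact
    maximum any resolved tree can require for this character."""
    cells = matrix.scored_column(char)
    if not cells:
        return 0.0
    states = _state_space(matrix, char)
    step = _step_cost(matrix.is_ordered(char), len(states))
    index = {s: k for k, s in enumerate(states)}
    best = _INF
    for r, _ in enumerate(states):
        total = 0.0
        for cell in cells:
            total += min(step[r, index[s]] for s in cell if s in index)
        best = min(best, total)
    return float(best)


@dataclass
class CharacterFit:
    """Per-character fit: steps on the tree (s), minimum (m), star-tree
    maximum (g), and the derived indices."""

    char_index: int          # 1-based
    s: float
    m: float
    g: float
    informative: bool

    @property
    def ci(self) -> float:
        return self.m / self.s if self.s > 0 else 1.0

    @property
    def ri(self) -> float:
        return (self.g - self.s) / (self.g - self.m) if self.g > self.m else 1.0

    @property
    def rc(self) -> float:
        return self.ci * self.ri


@dataclass
class TreeFitStats:
    """Ensemble fit of a tree to a matrix."""

    length: float
    CI: float
    RI: float
    HI: float
    RC: float
    per_character: list[CharacterFit]
    excluded_uninformative: bool = False


def tree_fit_indices(tree: Tree, matrix: CharacterMatrix,
                     exclude_uninformative: bool = False,
                     reported_length: Optional[float] = None) -> TreeFitStats:
    """Ensemble CI/RI/HI/RC for a tree–matrix pair.

    ``exclude_uninformative`` drops characters with g == m from the CI/HI
    (and length) sums as well; by default they are included there, while the
    RI sums always exclude them (they contribute 0/0).  ``reported_length``
    substitutes a published total length for Σs in the ensemble indices —
    useful to recompute indices exactly as printed alongside a published
    tree length without rescoring on the (possibly unavailable) tree.
    """
    fits = []
    for c in range(1, matrix.n_characters + 1):
        m = char_min_steps(matrix, c)
        g = char_max_steps(matrix, c)
        s = character_length(tree, matrix, c) if tree is not None else m
        fits.append(CharacterFit(c, s=s, m=m, g=g, informative=g > m))

    pool = [f for f in fits if f.informative] if exclude_uninformative else fits
    sum_s = sum(f.s for f in pool)
    sum_m = sum(f.m for f in pool)
    if reported_length is not None:
        # published totals include every character
        sum_s = reported_length
        if exclude_uninformative:
            sum_s = reported_length - sum(f.s for f in fits if not f.informative)
    info = [f for f in fits if f.informative]
    sum_g_i = sum(f.g for f in info)
    sum_m_i = sum(f.m for f in info)
    sum_s_i = sum_s - (sum(f.m for f in pool if not f.informative))
    # uninformative characters always realize s == m == g on any tree
    ci = sum_m / sum_s if sum_s > 0 else 1.0
    ri = ((sum_g_i - sum_s_i) / (sum_g_i - sum_m_i)
          if sum_g_i > sum_m_i else 1.0)
    return TreeFitStats(length=sum_s, CI=ci, RI=ri, HI=1.0 - ci, RC=ci * ri,
                        per_character=fits,
                        excluded_uninformative=exclude_uninformative)


@dataclass(frozen=True)
class Synapomorphy:
    char_index: int                    # 1-based
    derived_states: tuple[int, ...]    # optimal state(s) at the clade node

    @property
    def derived_state(self) -> int:
        return self.derived_states[0]


def _out_vectors(tree: Tree, down: dict[Node, np.ndarray],
                 step: np.ndarray) -> dict[Node, np.ndarray]:
    """Out[v][s]: minimum cost of everything outside v's subtree, including
    the branch to v's parent, given v has state s.  Out[root] = 0."""
    out: dict[Node, np.ndarray] = {tree.root: np.zeros(step.shape[0])}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        child_mins = {c: np.min(down[c][None, :] + step, axis=1)
                      for c in node.children}
        total = sum(child_mins.values())
        for child in node.children:
            # parent state t: out[node][t] + siblings' contributions
            parent_given = out[node] + total - child_mins[child]
            out[child] = np.min(parent_given[:, None] + step, axis=0)
    return out


def unambiguous_synapomorphies(tree: Tree, matrix: CharacterMatrix,
                               node: Node) -> list[Synapomorphy]:
    """Characters whose every minimum-cost reconstruction places a change on
    the branch subtending *node*.

    Membership is decided by re-running the DP with the branch's endpoints
    constrained equal: if the constrained optimum exceeds the unconstrained
    optimum, a change on that branch is unavoidable.  The reported derived
    states are the node's states across optimal reconstructions.
    """
    if node.parent is None:
        raise ValueError("the root subtends no branch")
    results = []
    for char in range(1, matrix.n_characters + 1):
        down, step, states = _down_pass(tree, matrix, char)
        out = _out_vectors(tree, down, step)
        totals = down[node] + out[node]
        optimum = float(np.min(totals))
        # constrain the branch ends equal: Out with the step on this branch
        # replaced by zero cost at equal states only
        parent = node.parent
        child_mins = {c: np.min(down[c][None, :] + step, axis=1)
                      for c in parent.children}
        parent_total = out[parent] + sum(child_mins.values()) - child_mins[node]
        constrained = float(np.min(parent_total + down[node]))
        if constrained > optimum + 1e-9:
            derived = tuple(states[k] for k in range(len(states))
                            if totals[k] <= optimum + 1e-9)
            results.append(Synapomorphy(char, derived))
    return results
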