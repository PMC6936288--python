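"""Seeded generators for trees, first-appearance data, discrete characters
and tip areas, with controlled congruence structure.

Every generator takes a :class:`SimulationConfig` and derives one local
``numpy`` random generator per call from ``config.seed`` (no global state),
so identical configs give bit-identical output.

The FAD generator is the interesting one: its ``congruence`` knob steers
the expected gap excess ratio of the (tree, FADs) pair.  At ``congruence=1``
it builds an assignment whose GER is exactly 1 on *any* topology: ages
decrease along one root-to-tip spine and all tips of each off-spine subtree
tie at their attachment age, so ghost lineages telescope to Gmin (a
balanced tree with all-distinct FADs provably cannot reach GER 1, so the
ties are essential, not a convenience).  Decreasing ``congruence`` promotes
a growing fraction of "donor" tips (one per lowest internal node) to the
root age; with every donor promoted, every internal node attains the oldest
age and MIG equals Gmax exactly (GER 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .characters import CharacterMatrix
from .occurrences import Occurrence, OccurrenceTable
from .tree import Node, Tree

__all__ = [
    "SimulationConfig", "simulate_tree", "simulate_fads",
    "permute_fads_null", "simulate_characters", "simulate_tip_areas",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all generators; only the relevant subset is read by each.

    Units: ``root_age`` in Ma, ``birth_rate`` per Myr, ``change_rate`` in
    expected state changes per character over the whole tree,
    ``area_switch_prob`` per branch.
    """

    n_tips: int = 16
    seed: int = 0
    root_age: float = 100.0
    birth_rate: float = 0.1
    congruence: float = 1.0
    n_characters: int = 100
    n_states: int = 3
    change_rate: float = 2.0
    missing_prob: float = 0.0
    polymorphism_prob: float = 0.0
    areas: tuple[str, ...] = ("NorthAmerica", "Europe")
    area_switch_prob: float = 0.1

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if not 0.0 <= self.congruence <= 1.0:
            raise ValueError("congruence must be in [0, 1]")
        for name in ("birth_rate", "change_rate", "missing_prob",
                     "polymorphism_prob", "area_switch_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.area_switch_prob > 1 or self.missing_prob > 1 \
                or self.polymorphism_prob > 1:
            raise ValueError("probabilities must be <= 1")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def simulate_tree(config: SimulationConfig) -> Tree:
    """Rooted binary tree from a pure-birth (Yule) process: starting from a
    two-tip root, a uniformly random extant tip is repeatedly bifurcated
    until ``n_tips`` tips exist.  Tips are labelled t01, t02, ... in
    left-to-right order."""
    rng = config.rng(salt=1)
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    while len(tips) < config.n_tips:
        k = int(rng.integers(len(tips)))
        tip = tips.pop(k)
        tips.append(tip.add_child(Node()))
        tips.append(tip.add_child(Node()))
    tree = Tree(root)
    width = len(str(config.n_tips))
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.label = f"t{i:0{width}d}"
    return tree


def _spine(tree: Tree) -> list[Node]:
    """Deterministic root-to-tip path: descend into the child with the most
    tips (ties: lexicographically smallest descendant tip label)."""
    path = [tree.root]
    node = tree.root
    while not node.is_leaf:
        node = min(node.children,
                   key=lambda c: (-sum(1 for _ in c.leaves()),
                                  min(c.tip_labels())))
        path.append(node)
    return path


def _congruent_fads(tree: Tree, config: SimulationConfig,
                    rng: np.random.Generator) -> dict[str, float]:
    """FAD assignment with GER exactly 1 on this topology."""
    path = _spine(tree)
    k = len(path)
    # strictly decreasing ages along the spine, strictly positive
    ages = np.sort(rng.uniform(0.05 * config.root_age, config.root_age,
                               size=k))[::-1]
    ages[0] = config.root_age
    fads: dict[str, float] = {}
    for depth, node in enumerate(path):
        if node.is_leaf:
            fads[node.label] = float(ages[depth])
            continue
        on_path_child = path[depth + 1]
        for child in node.children:
            if child is on_path_child:
                continue
            for leaf in child.leaves():
                fads[leaf.label] = float(ages[depth])
    return fads


def _donor_tips(tree: Tree) -> list[str]:
    """One tip per lowest internal node (all children are tips).  Every
    internal node's subtree contains such a node, so giving all donors the
    oldest age forces every internal node to the oldest age."""
    donors = []
    for node in tree.internal_nodes():
        if all(c.is_leaf for c in node.children):
            donors.append(min(c.label for c in node.children))
    return sorted(donors)


def _incongruent_fads(tree: Tree, config: SimulationConfig,
                      rng: np.random.Generator) -> dict[str, float]:
    """FAD assignment with GER exactly 0: every donor tip carries the
    oldest age, so every internal node attains the oldest age and MIG
    telescopes to Gmax; all other tips draw distinct younger ages."""
    oldest = config.root_age
    donors = set(_donor_tips(tree))
    others = sorted(tree.tip_labels() - donors)
    values = rng.uniform(0.05 * oldest, 0.95 * oldest, size=len(others))
    fads = {t: oldest for t in donors}
    fads.update({t: float(v) for t, v in zip(others, values)})
    return fads


def simulate_fads(tree: Tree, config: SimulationConfig) -> OccurrenceTable:
    """First appearances whose stratigraphic congruence with *tree* is
    steered by ``config.congruence`` (see module docstring).

    At the extremes the dedicated constructions give GER exactly 1 and 0.
    In between, a fraction (1 - congruence) of the donor tips is promoted
    to the root age starting from the congruent assignment, moving MIG
    smoothly from Gmin toward Gmax; a promotion is skipped when it would
    leave fewer than two tips strictly younger than the oldest age (which
    would make GER undefined).  FADs are strictly positive; LAD defaults
    to the FAD.
    """
    rng = config.rng(salt=2)
    if config.congruence == 0.0:
        fads = _incongruent_fads(tree, config, rng)
    else:
        fads = _congruent_fads(tree, config, rng)
        donors = _donor_tips(tree)
        # continuous dose: full promotions plus one fractional promotion
        dose = (1.0 - config.congruence) * len(donors)
        n_full = int(dose)
        frac = dose - n_full
        oldest = config.root_age
        order = [int(i) for i in rng.permutation(len(donors))]
        for rank, k in enumerate(order):
            if rank >= n_full + (1 if frac > 0 else 0):
                break
            tip = donors[k]
            n_younger = sum(1 for f in fads.values() if f < oldest)
            if fads[tip] < oldest and n_younger <= 2:
                continue
            if rank < n_full:
                fads[tip] = oldest
            else:
                fads[tip] = fads[tip] + frac * (oldest - fads[tip])
    return OccurrenceTable.from_records(
        Occurrence(t, fad, fad) for t, fad in sorted(fads.items()))


def permute_fads_null(table: OccurrenceTable, n: int,
                      seed: int) -> list[OccurrenceTable]:
    """*n* copies of *table* with (FAD, LAD) pairs permuted across taxa.

    The multiset of FADs is preserved exactly, so Gmin and Gmax are
    invariant across the null set; areas stay with their taxa."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng((seed, 3))
    taxa = sorted(table.taxa)
    pairs = [(table[t].fad, table[t].lad) for t in taxa]
    out = []
    for _ in range(n):
        perm = rng.permutation(len(taxa))
        records = []
        for t, k in zip(taxa, perm):
            fad, lad = pairs[int(k)]
            rec = table[t]
            records.append(Occurrence(t, fad, lad, rec.area, rec.provenance))
        out.append(OccurrenceTable.from_records(records))
    return out


def simulate_characters(tree: Tree, config: SimulationConfig) -> CharacterMatrix:
    """Unordered k-state characters evolved by a symmetric change process.

    Per character, each branch carries a Poisson(change_rate / n_branches)
    number of change events; each event moves to a uniformly chosen
    different state, so the expected number of true changes per character is
    ``change_rate``.  True change counts are recorded on the returned
    matrix (``true_changes``), and parsimony length can never exceed them.
    Missing data and an extra polymorphic state are injected at the stated
    per-cell probabilities afterwards.
    """
    rng = config.rng(salt=4)
    branches = [n for n in tree.postorder() if n.parent is not None]
    rate = config.change_rate / len(branches)
    taxa = sorted(tree.tip_labels())
    columns: list[dict[str, frozenset[int]]] = []
    raw_cols: list[dict[str, str]] = []
    true_changes = []
    symbols = {i: str(i) for i in range(config.n_states)}
    for _ in range(config.n_characters):
        state = {tree.root: int(rng.integers(config.n_states))}
        changes = 0
        for node in tree.preorder():
            if node.parent is None:
                continue
            s = state[node.parent]
            for _ in range(rng.poisson(rate)):
                if config.n_states > 1:
                    shift = 1 + int(rng.integers(config.n_states - 1))
                    s = (s + shift) % config.n_states
                    changes += 1
            state[node] = s
        col, raw = {}, {}
        for leaf in tree.leaves():
            s = state[leaf]
            if rng.random() < config.missing_prob:
                col[leaf.label], raw[leaf.label] = None, "?"
            elif rng.random() < config.polymorphism_prob and config.n_states > 1:
                extra = (s + 1 + int(rng.integers(config.n_states - 1))) \
                    % config.n_states
                pair = frozenset({s, extra})
                col[leaf.label] = pair
                raw[leaf.label] = "".join(symbols[x] for x in sorted(pair))
            else:
                col[leaf.label] = frozenset({s})
                raw[leaf.label] = symbols[s]
        columns.append(col)
        raw_cols.append(raw)
        true_changes.append(changes)
    # assemble: expand missing cells to each character's observed universe
    cells, raws = [], []
    universes = []
    for col in columns:
        obs = set()
        for v in col.values():
            if v:
                obs |= v
        universes.append(frozenset(obs) if obs else frozenset({0}))
    for t in taxa:
        row, rrow = [], []
        for j, (col, raw) in enumerate(zip(columns, raw_cols)):
            if col[t] is None:
                row.append(universes[j])
            else:
                row.append(col[t])
            rrow.append(raw[t])
        cells.append(row)
        raws.append(rrow)
    matrix = CharacterMatrix(taxa, cells, raws,
                             symbol_map={str(i): i for i in range(config.n_states)})
    matrix.true_changes = true_changes
    return matrix


def simulate_tip_areas(tree: Tree, config: SimulationConfig) -> dict[str, str]:
    """Tip -> area labels from a root draw plus per-branch switching.

    The root's area is drawn uniformly; each branch switches to a uniformly
    chosen different area with probability ``area_switch_prob``."""
    if not config.areas:
        raise ValueError("need at least one area label")
    rng = config.rng(salt=5)
    areas = list(config.areas)
    state = {tree.root: areas[int(rng.integers(len(areas)))]}
    for node in tree.preorder():
        if node.parent is None:
            continue
        a = state[node.parent]
        if len(areas) > 1 and rng.random() < config.area_switch_prob:
            others = [x for x in areas if x != a]
            a = others[int(rng.integers(len(others)))]
        state[node] = a
    return {leaf.label: state[leaf] for leaf in tree.leaves()}
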