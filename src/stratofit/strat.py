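"""Stratigraphic congruence: ghost lineages, MIG, Gmin, Gmax and the gap
excess ratio (GER).

Given a rooted topology and first-appearance data (FADs, Ma), every node is
dated by the oldest FAD among its tip descendants.  Each branch then implies
a ghost lineage — a span of time during which the lineage must have existed
(because its sister appears earlier) but has no fossil record — of duration
``age(parent) - age(child)``.  Summing over branches gives the minimum
implied gap (MIG).  For a fixed set of FADs the best any topology can do is

    Gmin = oldest FAD - youngest FAD,

attained by a pectinate tree with taxa nested youngest-inward, and the worst
is

    Gmax = sum over non-oldest taxa of (oldest FAD - taxon FAD),

attained when the oldest taxon is maximally nested.  The gap excess ratio

    GER = 1 - (MIG - Gmin) / (Gmax - Gmin)

is 1 for a perfectly congruent topology and 0 for the least congruent one.
FADs only: last appearances never enter these quantities.

Polytomies are treated as hard (every child dated against the polytomous
parent); :func:`resolve_polytomy_min_mig` provides the soft alternative,
replacing each polytomy by its MIG-minimal binary resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import DegenerateStratigraphyError, OccurrenceError
from .occurrences import OccurrenceTable, reconcile
from .tree import Node, Tree

__all__ = [
    "GERResult", "node_min_ages", "minimum_implied_gap", "g_min", "g_max",
    "gap_excess_ratio", "compare_topologies", "resolve_polytomy_min_mig",
]


@dataclass
class GERResult:
    """GER decomposition for one topology.

    All durations in Myr; ``branch_gaps`` maps the child-end node id of each
    branch to its ghost-lineage duration, ``node_ages`` maps node ids to
    minimum ages in Ma.
    """

    mig: float
    g_min: float
    g_max: float
    ger: float
    branch_gaps: dict[str, float] = field(default_factory=dict)
    node_ages: dict[str, float] = field(default_factory=dict)


def _check_fads(tree: Tree, table: OccurrenceTable) -> None:
    missing = sorted(tree.tip_labels() - table.taxa)
    if missing:
        raise OccurrenceError(f"tips without FADs: {missing}")


def node_min_ages(tree: Tree, table: OccurrenceTable) -> dict[Node, float]:
    """Date every node by the oldest FAD among its tip descendants.

    Tip age = its FAD; internal age = max over children; the root carries
    the oldest FAD overall.  Ages never decrease from child to parent.
    """
    _check_fads(tree, table)
    ages: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            ages[node] = table.fad(node.label)
        else:
            ages[node] = max(ages[c] for c in node.children)
        node.annotations["age"] = ages[node]
    return ages


def minimum_implied_gap(tree: Tree, table: OccurrenceTable
                        ) -> tuple[float, dict[str, float]]:
    """Sum of ghost-lineage durations implied by the topology (MIG, Myr),
    with the per-branch breakdown keyed by child-node id.

    Polytomies are hard: each child of a polytomous node is dated against
    that node's age directly.
    """
    ages = node_min_ages(tree, table)
    ids = tree.node_ids()
    gaps: dict[str, float] = {}
    for node in tree.postorder():
        for child in node.children:
            gaps[ids[child]] = ages[node] - ages[child]
    return sum(gaps.values()), gaps


def _fad_values(table: OccurrenceTable) -> list[float]:
    if len(table) < 2:
        raise OccurrenceError("need at least 2 taxa with FADs")
    return [r.fad for r in table.records.values()]


def g_min(table: OccurrenceTable) -> float:
    """Theoretical minimum summed ghost lineage over all topologies:
    oldest FAD minus youngest FAD."""
    fads = _fad_values(table)
    return max(fads) - min(fads)


def g_max(table: OccurrenceTable) -> float:
    """Maximum summed ghost lineage: sum over every non-oldest taxon of
    (oldest FAD - taxon FAD).  Taxa tied for oldest contribute 0."""
    fads = _fad_values(table)
    oldest = max(fads)
    return sum(oldest - f for f in fads)


def gap_excess_ratio(tree: Tree, table: OccurrenceTable) -> GERResult:
    """GER = 1 - (MIG - Gmin)/(Gmax - Gmin) for one topology.

    Raises :class:`DegenerateStratigraphyError` when all FADs coincide
    (Gmax == Gmin), where the ratio is undefined.
    """
    table = table.subset(tree.tip_labels())
    mig, gaps = minimum_implied_gap(tree, table)
    gmin, gmax = g_min(table), g_max(table)
    if gmax <= gmin:
        raise DegenerateStratigraphyError(
            "all first appearances coincide (Gmax == Gmin); GER undefined")
    ger = 1.0 - (mig - gmin) / (gmax - gmin)
    ids = tree.node_ids()
    ages = {ids[n]: n.annotations["age"] for n in tree.postorder()}
    return GERResult(mig=mig, g_min=gmin, g_max=gmax, ger=ger,
                     branch_gaps=gaps, node_ages=ages)


TreesArg = Union[dict, Sequence[tuple[str, Tree]]]


def compare_topologies(trees: TreesArg, table: OccurrenceTable,
                       scope: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Score competing topologies against one occurrence table.

    Each tree is pruned (reconcile mode ``prune``) to its own intersection
    with the table (and the optional *scope* taxon subset); Gmin/Gmax are
    computed on each tree's surviving taxa, so ``n_taxa`` is reported to
    keep rows with different coverage from being compared naively.  Rows are
    sorted by GER descending; all trees tied for the best GER are flagged.
    """
    if isinstance(trees, dict):
        items = list(trees.items())
    else:
        items = list(trees)
    if not items:
        raise ValueError("no trees to compare")
    rows = []
    for name, tree in items:
        subset = table if scope is None else table.subset(scope)
        pruned, sub = reconcile(tree, subset, mode="prune")
        res = gap_excess_ratio(pruned, sub)
        rows.append({"tree": name, "n_taxa": pruned.n_tips, "mig": res.mig,
                     "g_min": res.g_min, "g_max": res.g_max, "ger": res.ger})
    frame = pd.DataFrame(rows).sort_values(
        ["ger", "tree"], ascending=[False, True], kind="mergesort")
    frame["best"] = frame["ger"] == frame["ger"].max()
    return frame.reset_index(drop=True)


def resolve_polytomy_min_mig(tree: Tree, table: OccurrenceTable) -> Tree:
    """Resolve every polytomy into the pectinate arrangement that minimizes
    MIG: children ordered by descending subtree age, oldest outermost.

    The returned tree's MIG never exceeds the input's, and for any one
    polytomy the pectinate-by-age resolution attains the minimum over all
    binary resolutions (the connecting gaps telescope to oldest child age
    minus youngest child age, which is a lower bound for any resolution).
    Age ties are broken by the lexicographically smallest descendant tip
    label, for determinism.
    """
    out = tree.copy()
    ages = node_min_ages(out, table.subset(out.tip_labels()))

    def sort_key(node: Node):
        return (-ages[node], min(node.tip_labels()))

    def resolve(node: Node) -> Node:
        node.children = [resolve(c) for c in node.children]
        while len(node.children) > 2:
            kids = sorted(node.children, key=sort_key)
            # join the two youngest into a new node, repeat
            a, b = kids[-2], kids[-1]
            joined = Node()
            joined.add_child(a)
            joined.add_child(b)
            ages[joined] = max(ages[a], ages[b])
            node.children = [k for k in kids[:-2]] + [joined]
        for c in node.children:
            c.parent = node
        return node

    return Tree(resolve(out.root))
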