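"""Ancestral-area probability propagation on a (possibly polytomous) tree.

Each tip is restricted to a single continent-level area — by convention the
area where the oldest material of that taxon was recovered — represented as
an indicator distribution.  Internal-node distributions are computed tip to
base: under the default ``mean`` rule a node's distribution is the equal-
weight arithmetic mean of its children's distributions (a polytomy averages
over all k children with weight 1/k).  Enumerating equiprobable child-area
scenarios by the elementary product and addition rules yields exactly this
recursion, and on binary trees it produces dyadic probabilities k/2^d
(e.g. 3/4, 5/8).  A normalized-product rule is available for sensitivity
checks; no dispersal model, rate matrix or area adjacency is assumed.
"""

from __future__ import annotations

import warnings
from typing import Optional

import pandas as pd

from .errors import OccurrenceError
from .occurrences import OccurrenceTable
from .tree import Node, Tree, normalize_label

__all__ = ["tip_area_distributions", "node_area_probabilities", "area_report"]

AreaDistribution = dict[str, float]


def tip_area_distributions(table: OccurrenceTable, tree: Tree
                           ) -> dict[str, AreaDistribution]:
    """Indicator distribution for every tip, over the closed-world area set
    (the union of areas observed at the tips).  Errors name any tip without
    an area label."""
    tips = sorted(tree.tip_labels())
    missing = [t for t in tips if t not in table or not table.area(t)]
    if missing:
        raise OccurrenceError(f"tips without an area label: {missing}")
    universe = sorted({table.area(t) for t in tips})
    return {t: {a: (1.0 if a == table.area(t) else 0.0) for a in universe}
            for t in tips}


def _combine_mean(dists: list[AreaDistribution]) -> AreaDistribution:
    k = len(dists)
    areas = dists[0]
    return {a: sum(d[a] for d in dists) / k for a in areas}


def _combine_product(dists: list[AreaDistribution]) -> AreaDistribution:
    prod = {}
    for a in dists[0]:
        p = 1.0
        for d in dists:
            p *= d[a]
        prod[a] = p
    total = sum(prod.values())
    if total == 0.0:
        # disjoint child supports: the product carries no signal; fall back
        return _combine_mean(dists)
    return {a: p / total for a, p in prod.items()}


_RULES = {"mean": _combine_mean, "product": _combine_product}


def node_area_probabilities(tree: Tree,
                            tips: dict[str, AreaDistribution],
                            rule: str = "mean") -> dict[Node, AreaDistribution]:
    """Post-order propagation of area distributions to every node.

    *tips* must cover all tree tips.  Every returned distribution sums to 1.
    The result is also attached to each node as ``annotations['areas']``.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {sorted(_RULES)}")
    combine = _RULES[rule]
    missing = sorted(tree.tip_labels() - set(tips))
    if missing:
        raise OccurrenceError(f"tips without area distributions: {missing}")
    dists: dict[Node, AreaDistribution] = {}
    for node in tree.postorder():
        if node.is_leaf:
            dists[node] = dict(tips[node.label])
        else:
            dists[node] = combine([dists[c] for c in node.children])
        node.annotations["areas"] = dists[node]
    return dists


def area_report(tree: Tree, dists: dict[Node, AreaDistribution],
                focal_clades: Optional[dict[str, list[str]]] = None
                ) -> pd.DataFrame:
    """Tabulate per-node area probabilities in deterministic post-order.

    *focal_clades* maps clade names to tip-label lists; each resolves to the
    MRCA of its tips.  On a consensus tree the MRCA may contain extra tips
    (strict monophyly is brittle there); that raises a warning and the MRCA
    row is reported with its actual tip count.
    """
    ids = tree.node_ids()
    areas = sorted(next(iter(dists.values())))
    rows = []
    for node in tree.postorder():
        row = {"node": ids[node], "clade": node.label if not node.is_leaf else None,
               "n_tips": 1 if node.is_leaf else len(node.tip_labels())}
        row.update({a: dists[node][a] for a in areas})
        rows.append(row)
    frame = pd.DataFrame(rows)
    if focal_clades:
        focal_rows = []
        for name, tip_set in focal_clades.items():
            node = tree.mrca(tip_set)
            extra = node.tip_labels() - {normalize_label(t) for t in tip_set}
            if extra:
                warnings.warn(
                    f"focal clade {name!r}: MRCA contains "
                    f"{len(extra)} extra tip(s) (e.g. {sorted(extra)[:3]})",
                    stacklevel=2)
            row = {"node": ids[node], "clade": name,
                   "n_tips": len(node.tip_labels())}
            row.update({a: dists[node][a] for a in areas})
            focal_rows.append(row)
        frame = pd.concat([pd.DataFrame(focal_rows), frame], ignore_index=True)
    return frame
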