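import pytest

from stratofit import Occurrence, OccurrenceTable, parse_newick


def make_table(labels, fads, areas=None):
    areas = areas or {}
    return OccurrenceTable.from_records(
        Occurrence(t, f, f, areas.get(t)) for t, f in zip(labels, fads))


@pytest.fixture
def ladder_tree():
    """Pectinate tree, oldest taxon outermost (perfectly congruent)."""
    return parse_newick("(A,(B,(C,D)));")


@pytest.fixture
def anti_ladder_tree():
    """Pectinate tree with the oldest taxon most nested (least congruent)."""
    return parse_newick("(D,(C,(B,A)));")


@pytest.fixture
def balanced_tree():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def fad_table():
    """FADs 10, 8, 5, 2 Ma for taxa A-D."""
    return make_table("ABCD", [10.0, 8.0, 5.0, 2.0])


def tuples_to_newick(tree):
    """Nested-tuple topology (oracles.py convention) -> Newick string."""
    if isinstance(tree, tuple):
        return "(" + ",".join(tuples_to_newick(t) for t in tree) + ")"
    return str(tree)


def as_package_tree(tree_tuples):
    return parse_newick(tuples_to_newick(tree_tuples) + ";")
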