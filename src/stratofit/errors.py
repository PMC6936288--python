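"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`StratofitError`, so callers (and the CLI) can distinguish domain
errors from programming errors.
"""


class StratofitError(Exception):
    """Base class for all stratofit errors."""


class TreeParseError(StratofitError):
    """Malformed Newick/NEXUS tree input (unbalanced parentheses, duplicate
    or empty tip labels, empty tree)."""


class MatrixParseError(StratofitError):
    """Malformed NEXUS character data (dimension mismatch, unknown state
    symbol, ragged matrix rows)."""


class OccurrenceError(StratofitError):
    """Invalid occurrence table (fad < lad, negative ages, duplicate taxa,
    missing columns)."""


class ReconcileError(StratofitError):
    """Taxon sets of a tree and an occurrence table cannot be reconciled."""


class DegenerateStratigraphyError(StratofitError):
    """All first appearances coincide (Gmax == Gmin), so the gap excess
    ratio is undefined."""
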