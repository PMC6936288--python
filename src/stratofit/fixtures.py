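"""Packaged americhelydian example: four competing topology hypotheses for
the arrangement of Late Cretaceous marine-turtle lineages, with a small
occurrence table of first appearances and continent-level areas.

The four hypotheses differ in where Protostegidae sits relative to the
chelonioid crown group:

* ``crown_protostegids`` — protostegids are highly derived crown
  chelonioids, sister to the dermochelyid lineage;
* ``stem_protostegids_cteno_cheloniid`` — protostegids are stem
  chelonioids and ctenochelyids fall inside Pan-Cheloniidae;
* ``stem_protostegids_cteno_sister`` — protostegids are stem chelonioids,
  ctenochelyids are the sister clade of crown Chelonioidea, and
  Allopleuron is the earliest stem dermochelyid;
* ``protostegids_outside_cryptodira`` — protostegids lie entirely outside
  the clade uniting chelydroids and chelonioids.

Dating a clade by a published maximum-age constraint taxon is realized
implicitly: a clade's age is the oldest FAD of its members, so the
constraint taxon is simply included as a tip (e.g. Eosphargis or
Allopleuron for the dermochelyid stem, Euclastes for the cheloniid stem).

Each occurrence record carries a ``provenance`` flag: ``published`` for values
fixed by published statements this example encodes (the Demopolis Chalk
range of Asmodochelys, 79-74.5 Ma), ``illustrative`` for order-of-magnitude
stand-ins consistent with the fossil record but not authoritative.  The
fixture demonstrates the machinery; it is not a substitute for the original
occurrence compilation.
"""

from __future__ import annotations

from .occurrences import Occurrence, OccurrenceTable
from .tree import Tree, parse_newick

__all__ = ["americhelydia_fixture", "FIXTURE_TREE_NAMES"]

_CTENO = ("(Ctenochelys_stenoporus,(Prionochelys_matutina,"
          "(Asmodochelys_parhami,Peritresius_ornatus)))")
_PROTO = "(Desmatochelys_padillai,Protostega_gigas)"
_CHELONIID = "(Euclastes_wielandi,Argillochelys_antiqua)"
_DERM = "(Eosphargis_breineri,Dermochelys_coriacea)"
_DERM_ALLO = f"(Allopleuron_hofmanni,{_DERM})"

_TREES = {
    # protostegids as derived crown chelonioids, sister to dermochelyids
    "crown_protostegids":
        f"(Chelydroidea,(Toxochelys_latiremis,({_CTENO},"
        f"({_CHELONIID},({_PROTO},{_DERM})))));",
    # protostegids on the chelonioid stem; ctenochelyids within Pan-Cheloniidae
    "stem_protostegids_cteno_cheloniid":
        f"(Chelydroidea,({_PROTO},(Toxochelys_latiremis,"
        f"(({_CTENO},{_CHELONIID}),{_DERM}))));",
    # preferred weighted-parsimony arrangement: protostegids on the stem,
    # ctenochelyids sister to the crown, Allopleuron a stem dermochelyid
    "stem_protostegids_cteno_sister":
        f"(Chelydroidea,({_PROTO},(Toxochelys_latiremis,({_CTENO},"
        f"({_CHELONIID},{_DERM_ALLO})))));",
    # protostegids excluded from the cryptodiran crown entirely
    "protostegids_outside_cryptodira":
        f"({_PROTO},(Chelydroidea,(Toxochelys_latiremis,({_CTENO},"
        f"({_CHELONIID},{_DERM})))));",
}

FIXTURE_TREE_NAMES = tuple(_TREES)

#         taxon                     fad     lad    area            provenance
_OCCURRENCES = [
    ("Asmodochelys_parhami",        79.0,   74.5,  "NorthAmerica", "published"),
    ("Ctenochelys_stenoporus",      84.0,   80.0,  "NorthAmerica", "illustrative"),
    ("Prionochelys_matutina",       84.0,   80.0,  "NorthAmerica", "illustrative"),
    ("Peritresius_ornatus",         72.0,   66.0,  "NorthAmerica", "illustrative"),
    ("Toxochelys_latiremis",        89.0,   84.0,  "NorthAmerica", "illustrative"),
    ("Desmatochelys_padillai",      120.0,  112.0, "SouthAmerica", "illustrative"),
    ("Protostega_gigas",            85.0,   80.0,  "NorthAmerica", "illustrative"),
    ("Chelydroidea",                72.0,   66.0,  "NorthAmerica", "illustrative"),
    ("Euclastes_wielandi",          69.0,   62.0,  "NorthAmerica", "illustrative"),
    ("Argillochelys_antiqua",       55.0,   48.0,  "Europe",       "illustrative"),
    ("Allopleuron_hofmanni",        67.0,   66.0,  "Europe",       "illustrative"),
    ("Eosphargis_breineri",         56.0,   54.0,  "Europe",       "illustrative"),
    ("Dermochelys_coriacea",        0.0,    0.0,   "Europe",       "illustrative"),
]


def americhelydia_fixture() -> tuple[dict[str, Tree], OccurrenceTable]:
    """The four named topology hypotheses and their occurrence table."""
    trees = {name: parse_newick(newick) for name, newick in _TREES.items()}
    table = OccurrenceTable.from_records(
        Occurrence(taxon, fad, lad, area, prov)
        for taxon, fad, lad, area, prov in _OCCURRENCES)
    return trees, table
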