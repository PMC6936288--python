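"""Infer ancestral geographic areas on a consensus tree.

Each fossil tip is restricted to the continent of its oldest material;
probabilities are averaged tip-to-base (a node's distribution is the mean
of its children's).  On a binary tree this yields dyadic fractions such as
3/4 and 5/8.  The report lists two focal clades: the sea-turtle crown group
and the node joining ctenochelyids to it.
"""

from stratofit import (americhelydia_fixture, area_report,
                       node_area_probabilities, tip_area_distributions)

trees, occurrences = americhelydia_fixture()
tree = trees["stem_protostegids_cteno_sister"]

tips = tip_area_distributions(occurrences, tree)
dists = node_area_probabilities(tree, tips, rule="mean")
focal = {
    "crown_Chelonioidea": ["Euclastes_wielandi", "Argillochelys_antiqua",
                           "Allopleuron_hofmanni", "Eosphargis_breineri",
                           "Dermochelys_coriacea"],
    "Ctenochelyidae_plus_crown": ["Ctenochelys_stenoporus",
                                  "Prionochelys_matutina",
                                  "Asmodochelys_parhami",
                                  "Peritresius_ornatus",
                                  "Euclastes_wielandi",
                                  "Argillochelys_antiqua",
                                  "Allopleuron_hofmanni",
                                  "Eosphargis_breineri",
                                  "Dermochelys_coriacea"],
}
report = area_report(tree, dists, focal_clades=focal)
print(report.head(2).round(4).to_string(index=False))
print()
for _, row in report.head(2).iterrows():
    top = max(("Europe", "NorthAmerica", "SouthAmerica"), key=row.get)
    print(f"{row['clade']}: most probable ancestral area {top} "
          f"({row[top]:.1%})")
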