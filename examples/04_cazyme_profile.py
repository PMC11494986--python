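"""Attribute CAZy families to classes and summarise counts per taxon.

Family strings like GH13_1 collapse to family GH13 and class GH (glycoside
hydrolase); totals are conserved across any aggregation rank.
"""

import pandas as pd

from flocprofiler import GeneTable, cazy_summary, parse_taxonomy
from flocprofiler.cazymes import class_totals

rows = [
    ("MAG_flavo", "g1", "cazyme", None, "GH13"),
    ("MAG_flavo", "g2", "cazyme", None, "GH13_1"),
    ("MAG_flavo", "g3", "cazyme", None, "GH43"),
    ("MAG_flavo", "g4", "cazyme", None, "PL1"),
    ("MAG_sapro", "g1", "cazyme", None, "GH16"),
    ("MAG_sapro", "g2", "cazyme", None, "CE1"),
    ("MAG_rhodo", "g1", "cazyme", None, "GT2"),
]
table = GeneTable(pd.DataFrame(
    rows, columns=["scope_id", "gene_id", "symbol", "ko_id", "cazy_family"]
).assign(unknown_symbol=False))

taxonomies = {
    "MAG_flavo": parse_taxonomy("d__Bacteria;p__Bacteroidota;c__Bacteroidia;"
                                "o__Flavobacteriales;f__Flavobacteriaceae;g__;s__"),
    "MAG_sapro": parse_taxonomy("d__Bacteria;p__Bacteroidota;c__Bacteroidia;"
                                "o__Chitinophagales;f__Saprospiraceae;g__;s__"),
    "MAG_rhodo": parse_taxonomy("d__Bacteria;p__Pseudomonadota;c__Alphaproteobacteria;"
                                "o__Rhodobacterales;f__Rhodobacteraceae;g__;s__"),
}

by_class, by_family = cazy_summary(table, taxonomies, rank="family")
print("class x family-of-origin counts:")
print(by_class)
print("\nfamily x taxon counts:")
print(by_family)
print("\nclass totals:", class_totals(by_class))
# 7 CAZyme genes in, 7 out: the two GH13 subfamily variants collapse into
# GH13, and the polysaccharide-degrader families carry the GH/PL classes.
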