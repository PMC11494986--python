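"""CAZyme family-to-class attribution and per-taxon count summaries.

CAZy families are written ``<class><family>[_<subfamily>]`` (GH13, PL1,
GH13_1); the leading letters name one of the six classes: glycoside
hydrolases (GH), glycosyltransferases (GT), polysaccharide lyases (PL),
carbohydrate esterases (CE), auxiliary activities (AA), and
carbohydrate-binding modules (CBM).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .community import UNCLASSIFIED_LABEL
from .errors import ValidationError
from .io import CAZY_PATTERN, GeneTable, Taxonomy

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")


def cazy_class(family_string: str) -> str:
    """Class label (GH/GT/PL/CE/AA/CBM) for a CAZy family; subfamilies collapse."""
    m = CAZY_PATTERN.match(str(family_string))
    if not m:
        raise ValidationError(f"unparseable CAZy family: {family_string!r}")
    return m.group(1)


def cazy_family(family_string: str) -> str:
    """Family without its subfamily suffix: GH13_1 -> GH13."""
    m = CAZY_PATTERN.match(str(family_string))
    if not m:
        raise ValidationError(f"unparseable CAZy family: {family_string!r}")
    return m.group(1) + m.group(2)


def cazy_summary(
    gene_table: GeneTable,
    taxonomies: Mapping[str, Taxonomy],
    rank: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-by-taxon and family-by-taxon CAZyme gene counts at one rank.

    Scopes without a taxonomy, or unclassified at ``rank``, are grouped under
    the ``unclassified`` sentinel.  The totals over all cells of either table
    equal the number of CAZy-annotated genes, whatever the rank.
    """
    rows = gene_table.cazy_rows()
    if rows.empty:
        empty = pd.DataFrame(dtype=int)
        return empty, empty.copy()

    def taxon_of(scope: str) -> str:
        tax = taxonomies.get(scope)
        if tax is None:
            return UNCLASSIFIED_LABEL
        return tax.label_at(rank) or UNCLASSIFIED_LABEL

    work = pd.DataFrame(
        {
            "taxon": rows["scope_id"].map(taxon_of),
            "class": rows["cazy_family"].map(cazy_class),
            "family": rows["cazy_family"].map(cazy_family),
        }
    )
    by_class = (
        work.groupby(["class", "taxon"]).size().unstack(fill_value=0).astype(int)
    )
    by_family = (
        work.groupby(["family", "taxon"]).size().unstack(fill_value=0).astype(int)
    )
    return by_class, by_family


def class_totals(by_class: pd.DataFrame) -> dict[str, int]:
    """Total gene count per CAZy class (zero-filled for absent classes)."""
    sums = by_class.sum(axis=1) if not by_class.empty else pd.Series(dtype=int)
    return {c: int(sums.get(c, 0)) for c in CAZY_CLASSES}
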