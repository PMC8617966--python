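"""Localization and functional categorization of proteins and genes.

Localization comes from annotation keywords ("Secreted", "Membrane",
"Endoplasmic reticulum"), with precedence secreted > membrane > ER for
multi-keyword entries.  Functional tags on secreted features combine the
keyword route (extracellular matrix, cytokine) with name-pattern routes:
collagens (COL<d>A<d>), MMPs/TIMPs (MMP<d> / TIMP<d>) and fibronectin
(FN1) are recognised by gene symbol and imply ECM membership, giving the
nested compositional structure secretome -> {cytokines, ECM, other
secreted} and ECM -> {fibronectin, collagens, MMPs/TIMPs, other ECM}.
Cytokine/ECM conflicts resolve to cytokine by default so the slices of a
composition stay disjoint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .transcriptomics import collapse_probes

logger = logging.getLogger(__name__)

SECRETED = "secreted"
MEMBRANE_LOC = "membrane"
ER_LOC = "endoplasmic_reticulum"
OTHER_LOC = "other"

TAG_ECM = "ECM"
TAG_CYTOKINE = "cytokine"
TAG_COLLAGEN = "collagen"
TAG_MMP_TIMP = "MMP/TIMP"
TAG_FIBRONECTIN = "fibronectin"
TAG_OTHER_SECRETED = "other_secreted"

_COLLAGEN_RE = re.compile(r"^COL\d+A\d+$", re.IGNORECASE)
_MMP_TIMP_RE = re.compile(r"^(MMP|TIMP)\d+$", re.IGNORECASE)
_FIBRONECTIN_RE = re.compile(r"^FN1$", re.IGNORECASE)

KW_SECRETED = "Secreted"
KW_MEMBRANE = "Membrane"
KW_ER = "Endoplasmic reticulum"
KW_ECM = "Extracellular matrix"
KW_CYTOKINE = "Cytokine"


@dataclass(frozen=True)
class CategoryAssignment:
    feature: str
    gene_symbol: str
    localization: str
    tags: frozenset[str]

    @property
    def is_secreted(self) -> bool:
        return self.localization == SECRETED

    def secretome_category(self) -> str | None:
        """Top-level disjoint secretome slice: cytokine / ECM / other secreted."""
        if not self.is_secreted:
            return None
        if TAG_CYTOKINE in self.tags:
            return TAG_CYTOKINE
        if TAG_ECM in self.tags:
            return TAG_ECM
        return TAG_OTHER_SECRETED

    def ecm_subcategory(self) -> str | None:
        """Disjoint ECM slice: fibronectin / collagen / MMP-TIMP / other ECM."""
        if TAG_ECM not in self.tags:
            return None
        for tag in (TAG_FIBRONECTIN, TAG_COLLAGEN, TAG_MMP_TIMP):
            if tag in self.tags:
                return tag
        return "other_ECM"

    def flat_category(self) -> str | None:
        """Finest disjoint secretome partition: cytokine, fibronectin,
        collagen, MMP/TIMP, other_ECM or other_secreted (None if not
        secreted).  Used for category-sum stimulation comparisons."""
        top = self.secretome_category()
        if top is None:
            return None
        if top == TAG_ECM:
            return self.ecm_subcategory()
        return top


def assign_localization(keywords: set[str] | frozenset[str]) -> str:
    """Keyword-based localization with precedence secreted > membrane > ER."""
    if KW_SECRETED in keywords:
        return SECRETED
    if KW_MEMBRANE in keywords:
        return MEMBRANE_LOC
    if KW_ER in keywords:
        return ER_LOC
    return OTHER_LOC


def assign_functional_tags(
    gene_symbol: str,
    keywords: set[str] | frozenset[str],
    localization: str,
    cytokine_wins: bool = True,
) -> frozenset[str]:
    """Functional tags for a secreted feature (empty set otherwise).

    Name-based tags (collagen, MMP/TIMP, fibronectin) imply ECM.  A
    feature carrying both cytokine and ECM evidence keeps only one of the
    two (``cytokine_wins`` selects which), so compositional slices stay
    disjoint.  Secreted features with no other tag fall back to
    other_secreted.
    """
    if localization != SECRETED:
        return frozenset()
    tags: set[str] = set()
    if _COLLAGEN_RE.match(gene_symbol):
        tags.add(TAG_COLLAGEN)
    if _MMP_TIMP_RE.match(gene_symbol):
        tags.add(TAG_MMP_TIMP)
    if _FIBRONECTIN_RE.match(gene_symbol):
        tags.add(TAG_FIBRONECTIN)
    if KW_ECM in keywords or tags:
        tags.add(TAG_ECM)
    if KW_CYTOKINE in keywords:
        if TAG_ECM in tags:
            if cytokine_wins:
                tags = {TAG_CYTOKINE}
            # else: keep the ECM tags, drop cytokine
        else:
            tags.add(TAG_CYTOKINE)
    if not tags:
        tags.add(TAG_OTHER_SECRETED)
    return frozenset(tags)


def assign_categories(
    annotation: pd.DataFrame, cytokine_wins: bool = True
) -> dict[str, CategoryAssignment]:
    """Categorize every row of an annotation table (accession, gene_symbol,
    semicolon-separated keywords) -> {accession: CategoryAssignment}."""
    out: dict[str, CategoryAssignment] = {}
    for row in annotation.itertuples(index=False):
        keywords = frozenset(k for k in str(row.keywords or "").split(";") if k)
        loc = assign_localization(keywords)
        tags = assign_functional_tags(row.gene_symbol, keywords, loc, cytokine_wins)
        out[row.accession] = CategoryAssignment(row.accession, row.gene_symbol, loc, tags)
    return out


def categorize_features(
    features: list[str], assignments: dict[str, CategoryAssignment]
) -> dict[str, CategoryAssignment]:
    """Restrict assignments to ``features``; unknown ids are categorized as
    localization "other" with a warning rather than failing."""
    out: dict[str, CategoryAssignment] = {}
    unknown = []
    for f in features:
        if f in assignments:
            out[f] = assignments[f]
        else:
            unknown.append(f)
            out[f] = CategoryAssignment(f, f, OTHER_LOC, frozenset())
    if unknown:
        logger.warning("%d features missing from annotation table: %s", len(unknown), unknown[:5])
    return out


def assignments_table(assignments: dict[str, CategoryAssignment]) -> pd.DataFrame:
    """Flat TSV-ready view: feature, gene_symbol, localization, tags."""
    return pd.DataFrame(
        [
            {
                "feature": a.feature,
                "gene_symbol": a.gene_symbol,
                "localization": a.localization,
                "tags": ";".join(sorted(a.tags)),
            }
            for a in assignments.values()
        ]
    ).sort_values("feature", ignore_index=True)


def map_genes_to_features(
    genes: list[str], probe_map: pd.DataFrame, control_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Map (possibly duplicated) gene symbols to one representative probe each.

    The representative is the probe with the highest control-sample mean
    (the probe-collapsing rule).  Returns a table (gene_symbol, probe_id,
    mapped); genes absent from the probe map get probe_id = NA.
    """
    unique_genes = list(dict.fromkeys(genes))
    relevant = probe_map[probe_map["gene_symbol"].isin(unique_genes)]
    present = relevant[relevant["probe_id"].isin(control_matrix.index)]
    if len(present):
        collapsed = collapse_probes(
            control_matrix.loc[control_matrix.index.isin(present["probe_id"])],
            present,
        )
        chosen = collapsed.chosen_probe
    else:
        chosen = pd.Series(dtype=object)
    rows = []
    for g in unique_genes:
        probe = chosen.get(g)
        rows.append({"gene_symbol": g, "probe_id": probe, "mapped": probe is not None})
    return pd.DataFrame(rows)
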