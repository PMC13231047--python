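"""Derivation of the two disease gene sets and their common hub genes.

Disease A (the expression-profiled disease) comes from a three-step
intersection: (1) direction-consistent DEGs between the two discovery
datasets under the moderated configuration, (2) intersection with the
direction-consistent DEGs of the second (unmoderated) configuration,
(3) intersection with the strongest trait-correlated co-expression module
genes of both datasets. Disease B (the literature-mined disease) comes
from dual-source association filtering: relevance score >= 10 in the
relevance source AND PubMed-ID count > 0 in the curation source.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["filter_disease_b", "derive_disease_a", "common_hubs", "key_hubs"]


def filter_disease_b(
    relevance_table: pd.DataFrame,
    curation_table: pd.DataFrame,
    relevance_min: float = 10.0,
    pmid_min: int = 1,
) -> list[str]:
    """Genes passing the relevance filter (>= relevance_min, inclusive) in
    source 1 AND the PMID filter (>= pmid_min, i.e. > 0 at the default) in
    source 2; intersection of the two filtered lists, deduplicated and
    sorted."""
    rel = set(
        relevance_table.loc[
            relevance_table["relevance"] >= relevance_min, "gene_id"
        ].astype(str)
    )
    cur = set(
        curation_table.loc[
            curation_table["pmid_count"] >= pmid_min, "gene_id"
        ].astype(str)
    )
    return sorted(rel & cur)


def derive_disease_a(
    consistent_degs: tuple[set[str], set[str]],
    degs_config2: tuple[set[str], set[str]],
    module_genes_1,
    module_genes_2,
) -> tuple[list[str], dict]:
    """Three-step intersection for the disease-A gene set.

    Returns the sorted gene list and a provenance record describing what
    each step contributed and removed.
    """
    up1, down1 = (set(s) for s in consistent_degs)
    up2, down2 = (set(s) for s in degs_config2)
    step1 = up1 | down1
    step2 = (up1 & up2) | (down1 & down2)
    step3 = set(module_genes_1) & set(module_genes_2)
    if not step3:
        logger.warning("module-gene intersection (step 3) is empty")
    result = sorted(step2 & step3)
    provenance = {
        "step1_consistent_degs": sorted(step1),
        "step2_after_config2": sorted(step2),
        "step3_module_intersection": sorted(step3),
        "removed_by_step2": sorted(step1 - step2),
        "removed_by_step3": sorted(step2 - step3),
        "final": result,
    }
    return result, provenance


def common_hubs(set_a, set_b) -> list[str]:
    """Common hub genes: sorted intersection of the two disease sets."""
    return sorted(set(set_a) & set(set_b))


def key_hubs(key_a, key_b) -> list[str]:
    """Key hub genes: intersection of the two single-disease triangulated
    key-hub sets."""
    return sorted(set(key_a) & set(key_b))
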