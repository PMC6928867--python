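"""Bundled worked-example data: the published spinal-cord homeobox findings.

These small constants reproduce the published cross-database evidence the
pipeline was built around: GTEx-style median TPM values for the 10 homeobox
genes overexpressed in the human spinal cord, their fold ratios versus brain
cortex in the Brain Net Europe two-group comparison, the curated list of
transcription-factor partners of those HOX proteins, the 12 TFs of the
multiple-sclerosis spinal-cord gliosis co-expression module, and the typed
edges of the HOXA5 / TGF-beta / androgen-receptor regulatory network.

They serve as worked examples and test fixtures; real analyses supply their
own current database exports.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import ExpressionColumn, ExpressionMatrix

#: CNS region labels with GTEx donor counts.
REGION_COLUMNS = [
    ExpressionColumn("Spinal Cord", group="spinal_cord", n_samples=159),
    ExpressionColumn("Cerebellum", group="brain", n_samples=241),
    ExpressionColumn("Hippocampus", group="brain", n_samples=197),
    ExpressionColumn("Brain Cortex", group="brain", n_samples=255),
]

#: Median TPM per region for the 10 spinal-cord-overexpressed homeobox genes.
SPINAL_CORD_MEDIAN_TPM: dict[str, tuple[float, float, float, float]] = {
    "HOXA2": (8.14, 0.0, 0.0, 0.0),
    "HOXA4": (29.14, 0.03, 0.0, 0.01),
    "HOXA5": (23.01, 0.08, 0.01, 0.02),
    "HOXB2": (20.31, 0.54, 0.19, 0.10),
    "HOXB3": (6.16, 0.17, 0.05, 0.04),
    "HOXB5": (8.52, 0.0, 0.0, 0.0),
    "HOXB6": (5.37, 0.0, 0.0, 0.0),
    "HOXB7": (15.82, 0.0, 0.05, 0.02),
    "HOXB8": (17.91, 0.0, 0.0, 0.0),
    "HOXD8": (5.41, 0.0, 0.0, 0.01),
}

#: Spinal cord / brain cortex fold ratios and Bonferroni-adjusted p-values
#: from the Brain Net Europe two-group comparison (10 vs 10 samples).
SPINAL_VS_CORTEX_RATIOS: dict[str, tuple[float, float]] = {
    "HOXA2": (15.49, 4.57e-7),
    "HOXA4": (58.62, 2.62e-6),
    "HOXA5": (234.90, 9.03e-6),
    "HOXB2": (41.46, 1.14e-7),
    "HOXB3": (2.58, 0.01),
    "HOXB5": (52.41, 0.002),
    "HOXB6": (1.74, 0.06),
    "HOXB7": (102.29, 2.47e-6),
    "HOXB8": (407.52, 0.009),
    "HOXD8": (13.42, 0.001),
}

#: Curated (HOX gene, TF partner) physical interactions; 15 rows, 14 distinct
#: TFs (PBX1 partners both HOXB7 and HOXB8).
HOX_TF_PARTNERS: tuple[tuple[str, str], ...] = (
    ("HOXA5", "DDIT3"),
    ("HOXA5", "FOXA2"),
    ("HOXA5", "FOXO1"),
    ("HOXA5", "SMAD1"),
    ("HOXA5", "SOX2"),
    ("HOXA5", "TWIST1"),
    ("HOXA5", "ZNF707"),
    ("HOXB5", "HOXC4"),
    ("HOXB5", "HRAS"),
    ("HOXB5", "NKX2-1"),
    ("HOXB6", "ALX4"),
    ("HOXB6", "TCF21"),
    ("HOXB7", "PBX1"),
    ("HOXB8", "PBX1"),
    ("HOXB8", "PBX3"),
)

#: The 7 transcription-factor partners of HOXA5.
HOXA5_TF_PARTNERS = frozenset(p for q, p in HOX_TF_PARTNERS if q == "HOXA5")

#: Size of the human TF catalog used as the enrichment universe.
TF_CATALOG_SIZE = 1211

#: The 12 TFs of the MS spinal-cord gliosis-associated co-expression module.
#: SMAD1 and SOX2 (HOXA5 partners) and the three second-shell partners AR,
#: GLIS3, NFIB are named in the published module; the remaining members are
#: not enumerated in the main text, so the count is what analyses rely on.
GLIOSIS_MODULE_TF_COUNT = 12
GLIOSIS_MODULE_NAMED_TFS = frozenset({"SMAD1", "SOX2", "AR", "GLIS3", "NFIB"})

#: Regulatory-network layers: physical interactions among HOXA5, SOX2 and
#: the TGF-beta pathway; androgen-receptor transcriptional silencing; and
#: promoter-motif-predicted HOXA5 binding targets.
PHYSICAL_EDGES: tuple[tuple[str, str], ...] = (
    ("HOXA5", "SMAD1"),
    ("HOXA5", "SOX2"),
    ("SMAD1", "AR"),
    ("SOX2", "AR"),
    ("SMAD1", "GLIS3"),
    ("SMAD1", "NFIB"),
    ("SMAD1", "SMAD4"),
    ("SMAD2", "SMAD4"),
    ("SMAD3", "SMAD4"),
    ("SMAD2", "TGFBR1"),
    ("SMAD3", "TGFBR1"),
    ("TGFBR1", "TGFBR2"),
    ("TGFB1", "TGFBR2"),
)

AR_REPRESSION_TARGETS = ("SOX2", "SMAD3", "TGFBR2", "TGFB1")
REPRESSION_EDGES: tuple[tuple[str, str], ...] = tuple(
    ("AR", target) for target in AR_REPRESSION_TARGETS)

HOXA5_PREDICTED_TARGETS = ("SMAD1", "SMAD3", "TGFB1", "TGFBR2")
PREDICTED_BINDING_EDGES: tuple[tuple[str, str], ...] = tuple(
    ("HOXA5", target) for target in HOXA5_PREDICTED_TARGETS)

NODE_ROLES: dict[str, str] = {
    "HOXA5": "hox",
    "SOX2": "tf",
    "AR": "receptor",
    "GLIS3": "tf",
    "NFIB": "tf",
    "SMAD1": "pathway_member",
    "SMAD2": "pathway_member",
    "SMAD3": "pathway_member",
    "SMAD4": "pathway_member",
    "TGFB1": "pathway_member",
    "TGFBR1": "receptor",
    "TGFBR2": "receptor",
}

#: GO terms screened for SMAD / androgen-receptor pathway antagonism.
SMAD_PATHWAY_TERMS = ("GO:0060391", "GO:0060392")  # (positive, negative) regulation
AR_PATHWAY_TERMS = ("GO:2000825", "GO:0060766")    # (positive, negative) regulation
GO_TERM_NAMES = {
    "GO:0060391": "Positive regulation of SMAD protein signal transduction",
    "GO:0060392": "Negative regulation of SMAD protein signal transduction",
    "GO:0060766": "Negative regulation of androgen receptor signaling pathway",
    "GO:2000825": "Positive regulation of androgen receptor activity",
}


def spinal_cord_median_matrix() -> ExpressionMatrix:
    """The 10-gene x 4-region median TPM matrix as an :class:`ExpressionMatrix`."""
    labels = [c.label for c in REGION_COLUMNS]
    df = pd.DataFrame.from_dict(SPINAL_CORD_MEDIAN_TPM, orient="index", columns=labels)
    return ExpressionMatrix(values=df, unit="TPM", columns=list(REGION_COLUMNS))


def hox_query_genes() -> frozenset[str]:
    """The 10 spinal-cord-overexpressed homeobox genes."""
    return frozenset(SPINAL_CORD_MEDIAN_TPM)
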