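"""Curated gene lists for tetralogy of Fallot (TOF).

Two reference lists are bundled as plain tuples:

* :data:`TOF_TRAINING_GENES` — 53 genes with clear evidence of causing TOF in
  humans (reviews, OMIM, StatPearls, multiple case reports).  This is the
  default training set for the rank-annotation scorer.
* :data:`ESTABLISHED_TOF_GENES` — genes in which cohort individuals carried
  pathogenic/likely-pathogenic sequence variants and whose TOF association was
  already established; together with the training set they form the default
  "known TOF gene" registry used to screen candidate genes for phenotypic
  expansion.
"""

from __future__ import annotations

TOF_TRAINING_GENES: tuple[str, ...] = (
    "ALDH1A2", "CACNA1C", "CFC1", "CHD4", "CHD7", "CITED2", "CXCR4",
    "DOCK6", "EP300", "FGF8", "FLNA", "FLT4", "FOXC1", "FOXC2", "FOXH1",
    "GATA4", "GATA5", "GATA6", "GDF1", "HAND1", "HAND2", "ISL1", "JAG1",
    "KDM6A", "KDR", "KMT2C", "KMT2D", "KRAS", "MESP1", "MKKS", "NAA15",
    "NFATC1", "NKX2-5", "NKX2-6", "NODAL", "NOTCH1", "NOTCH2", "PITX2",
    "PTPN11", "RAF1", "RBM10", "ROBO1", "SALL1", "SMAD4", "SMARCC2",
    "SOS1", "TBX1", "TBX2", "TBX5", "TBX20", "TDGF1", "WASHC5", "ZFPM2",
)

ESTABLISHED_TOF_GENES: tuple[str, ...] = (
    "BRAF", "CDK13", "CHD4", "CHD7", "DOCK6", "EP300", "FLT4", "FOXC2",
    "JAG1", "KMT2D", "NAA15", "NOTCH1", "RBM10", "SMAD4", "SMARCA4",
    "WASHC5",
)


def known_tof_genes() -> frozenset[str]:
    """Union of the training set and the established TOF genes."""
    return frozenset(TOF_TRAINING_GENES) | frozenset(ESTABLISHED_TOF_GENES)
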