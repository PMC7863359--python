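"""Canonical names of the 46 signaling pathways (45 KEGG signaling pathways
plus the cell-cycle process) modelled by the network."""

SIGNALING_PATHWAYS_46: tuple[str, ...] = (
    "MAPK",
    "FoxO",
    "TGF-beta",
    "T cell receptor",
    "Adipocytokine",
    "ErbB",
    "Sphingolipid",
    "VEGF",
    "B cell receptor",
    "Oxytocin",
    "Ras",
    "Phospholipase D",
    "Apelin",
    "Fc epsilon RI",
    "Glucagon",
    "Rap1",
    "p53",
    "Hippo",
    "TNF",
    "Relaxin",
    "Calcium",
    "mTOR",
    "Toll-like receptor",
    "Neurotrophin",
    "AGE-RAGE",
    "cGMP-PKG",
    "PI3K-Akt",
    "NOD-like receptor",
    "Insulin",
    "Cell cycle",
    "cAMP",
    "AMPK",
    "RIG-I-like receptor",
    "GnRH",
    "Chemokine",
    "Wnt",
    "C-type lectin receptor",
    "Estrogen",
    "NF-kappa B",
    "Notch",
    "JAK-STAT",
    "Prolactin",
    "HIF-1",
    "Hedgehog",
    "IL-17",
    "Thyroid hormone",
)
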