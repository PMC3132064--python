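"""Published reference tables from the motivating discordant-twin study.

These small in-print tables are inputs to the worked examples: the signed
fold changes of the probes differentially expressed between probands and
matched controls, their functional category membership, and the qPCR
validation panel comparing RQ-PCR and microarray fold changes.
"""

from __future__ import annotations

import pandas as pd

from .qpcr import ConcordanceRow

# Signed fold changes (proband vs matched controls) of the annotated
# differentially expressed genes, split by direction of regulation.
_INCREASED = [
    ("TNFAIP6", 2.2), ("HP", 2.2), ("HPR", 2.3), ("ANXA3", 2.8),
    ("APOBEC3A", 1.4), ("EIF2AK2", 2.4), ("BMX", 2.2), ("CEACAM6", 4.7),
    ("PLSCR1", 2.3), ("LTF", 2.3), ("TNFSF10", 1.6), ("OASL", 2.2),
    ("MAP2K6", 1.4), ("ZCCHC2", 1.5), ("INHBB", 2.3), ("DEFA4", 2.3),
    ("IFI27", 7.2), ("SLC22A4", 1.7), ("IL1RN", 1.7), ("RRAGD", 1.3),
    ("DEGS1", 1.1), ("PGAP1", 1.3), ("F5", 1.4), ("CDS2", 1.2),
    ("HIST1H2AB", 1.3),
]
_DECREASED = [
    ("PACSIN1", -1.4), ("KRTCAP2", -1.2), ("FCER1A", -1.9), ("FYN", -1.3),
    ("SYTL2", -1.5), ("CD99", -1.2), ("PECI", -1.3), ("CD81", -1.2),
    ("PBX4", -1.4), ("DYRK2", -1.2), ("ZBTB5", -1.2), ("PABPC3", -1.3),
    ("NELL2", -1.3), ("LOC100133315", -1.2), ("DNAJA3", -1.3),
    ("EIF3S6IP", -1.3), ("EIF3S8", -1.2), ("RBMX", -1.1), ("GZMK", -1.4),
    ("DNMT1", -1.3), ("ZNF219", -1.2), ("DVL1", -1.2), ("IMP3", -1.2),
    ("ANAPC5", -1.2), ("AOF2", -1.2), ("GPRASP1", -1.4), ("LTK", -1.3),
    ("MTA1", -1.2), ("UXT", -1.2), ("KLRB1", -1.6), ("SEMA4C", -1.3),
    ("STMN3", -1.4), ("ATP1A1", -1.2), ("PSBP", -1.3), ("RPL18", -1.3),
    ("RNF220", -1.1), ("SPOCK2", -1.2), ("DDX28", -1.2), ("SRP46", -1.3),
    ("EIF3S7", -1.2), ("TNFRSF25", -1.3), ("MYBL1", -1.4), ("UBE2I", -1.1),
    ("PABPC1", -1.3), ("LDOC1L", -1.4), ("LGR6", -1.6), ("AES", -1.1),
    ("CXCR3", -1.3), ("ATP5G2", -1.2), ("RPLP2", -1.3), ("TC2N", -1.4),
    ("ERGIC3", -1.2), ("GPR183", -1.5), ("CSNK1E", -1.2), ("CRIP1", -1.3),
    ("ARIH2", -1.1), ("POLS", -1.2), ("PUF60", -1.2), ("MFNG", -1.2),
    ("PRPSAP2", -1.2), ("STAG3", -1.3), ("FBL", -1.2), ("RPS19", -1.3),
    ("DDB1", -1.2), ("FBXO21", -1.2), ("PTDSS1", -1.2), ("AKR1B1", -1.2),
]

# Functional category membership of the same genes.
FUNCTIONAL_CATEGORIES: dict[str, list[str]] = {
    "Immune": [
        "TNFAIP6", "PLSCR1", "LTF", "TNFSF10", "IFI27", "IL1RN", "FCER1A",
        "SYTL2", "CD99", "CD81", "GZMK", "LTK", "KLRB1", "TNFRSF25", "CXCR3",
    ],
    "Signaling": [
        "ANXA3", "APOBEC3A", "BMX", "CEACAM6", "OASL", "MAP2K6", "INHBB",
        "DEFA4", "RRAGD", "PGAP1", "PACSIN1", "FYN", "DYRK2", "LOC100133315",
        "GPRASP1", "STMN3", "ATP1A1", "PSBP", "UBE2I", "LGR6", "TC2N",
        "GPR183", "CSNK1E", "ARIH2", "PUF60", "FBXO21", "F5",
    ],
    "Gene expression": [
        "EIF2AK2", "PBX4", "ZBTB5", "PABPC3", "EIF3S6IP", "EIF3S8", "RBMX",
        "ZNF219", "IMP3", "AOF2", "MTA1", "UXT", "RPL18", "DDX28", "SRP46",
        "EIF3S7", "MYBL1", "PABPC1", "AES", "RPLP2", "FBL", "RPS19",
    ],
    "Metabolism": [
        "DEGS1", "CDS2", "PECI", "DNMT1", "ATP5G2", "POLS", "MFNG",
        "PRPSAP2", "PTDSS1", "AKR1B1",
    ],
    "Transport": ["HP", "HPR", "SLC22A4", "DNAJA3", "CRIP1"],
    "Structural": ["HIST1H2AB", "KRTCAP2", "SPOCK2"],
    "Cell cycle": ["NELL2", "DVL1", "ANAPC5", "SEMA4C", "ERGIC3", "STAG3"],
    "Other/Unknown": ["ZCCHC2", "RNF220", "LDOC1L", "DDB1"],
}

# qPCR validation panel: signed folds (vs matched controls) by assay and group.
_QPCR = [
    # gene, rq_affected, rq_unaffected, array_affected, array_unaffected
    ("TNFAIP6", 3.04, 2.17, 2.24, 2.15),
    ("TNFSF10", 1.50, 1.37, 1.58, 1.33),
    ("MAP2K6", 1.20, 1.20, 1.38, 1.21),
    ("IL1RN", 1.37, 1.21, 1.67, 1.17),
    ("IFI27", 1.20, 2.01, 7.24, 6.21),
    ("ANXA3", 3.18, 1.82, 2.79, 2.43),
    ("CEACAM6", 5.70, 1.15, 4.70, 1.10),
    ("DEFA4", 7.01, 1.47, 2.32, 1.18),
    ("EIF2AK2", 2.20, 1.12, 2.36, 1.70),
    ("FCERA1", -1.82, -1.48, -1.76, -1.22),
    ("SYTL2", -1.93, -1.61, -1.49, -1.10),
    ("LGR6", -1.25, -1.13, -1.64, -1.11),
    ("KRTCAP2", -1.20, -1.20, -1.16, -1.07),
    ("LTK", 1.02, 1.21, 2.32, 1.06),
    ("FYN", 1.23, 1.19, -1.26, -1.01),
]


def differential_fold_table() -> pd.DataFrame:
    """Signed fold changes of the differentially expressed genes."""
    rows = [(g, f, "up") for g, f in _INCREASED] + [
        (g, f, "down") for g, f in _DECREASED
    ]
    return pd.DataFrame(rows, columns=["gene", "fold", "direction"])


def functional_category_counts() -> pd.DataFrame:
    """Genes per functional category with the category fraction."""
    total = sum(len(v) for v in FUNCTIONAL_CATEGORIES.values())
    return pd.DataFrame(
        [
            {"category": c, "n_genes": len(v), "fraction": len(v) / total}
            for c, v in FUNCTIONAL_CATEGORIES.items()
        ]
    )


def qpcr_validation_table() -> pd.DataFrame:
    """qPCR vs microarray signed folds for the 15-gene validation panel."""
    return pd.DataFrame(
        _QPCR,
        columns=[
            "gene",
            "rq_affected",
            "rq_unaffected",
            "array_affected",
            "array_unaffected",
        ],
    )


def qpcr_concordance_rows(group: str = "affected") -> list[ConcordanceRow]:
    """Validation panel as concordance rows for the chosen subject group."""
    if group not in ("affected", "unaffected"):
        raise ValueError("group must be 'affected' or 'unaffected'")
    return [
        ConcordanceRow(gene=g, rq_fold=rq_a if group == "affected" else rq_u,
                       array_fold=ar_a if group == "affected" else ar_u)
        for g, rq_a, rq_u, ar_a, ar_u in _QPCR
    ]
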