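"""Published reference log2 fold changes for bovine lameness blood miRNAs.

Per-contrast log2 fold changes of the differentially expressed blood miRNAs
reported for feedlot cattle with four lameness phenotypes (digital dermatitis
DD, foot rot FR, toe tip necrosis TTN, and the FR+DD combination FRDD) versus
healthy controls (HC) at the pre-treatment week, and for unrecovered (UNR)
versus recovered (RE) cattle at individual weeks. These printed values are
inputs for worked examples and concordance checks: feeding each contrast's
values through direction-wise summarisation reproduces the study's reported
per-phenotype averages (e.g. DD vs HC downregulated mean -1.32).
"""

# pre-treatment (W0) lameness phenotype vs healthy control
W0_DE_LOG2FC: dict[str, dict[str, float]] = {
    "DD_vs_HC": {
        "bta-miR-6119-3p": -1.5,
        "bta-miR-2408": -1.46,
        "bta-miR-340": -1.01,
    },
    "FR_vs_HC": {
        "bta-miR-6119-3p": -1.29,
        "bta-miR-125a": -1.01,
        "bta-miR-200c": 1.14,
        "bta-miR-30a-5p": 1.17,
        "bta-miR-10225a": 1.31,
        "bta-miR-206": 1.81,
        "bta-miR-133a": 2.45,
    },
    "FRDD_vs_HC": {
        "bta-miR-6119-3p": -1.75,
        "bta-miR-1434-3p": -1.58,
        "bta-miR-211": -1.23,
        "bta-miR-1246": -1.09,
        "bta-miR-125a": -1.09,
        "bta-miR-484": -1.08,
        "bta-miR-92b": -1.07,
        "bta-miR-1306": -1.03,
        "bta-miR-2378": 1.03,
        "bta-miR-338": 1.04,
        "bta-miR-497": 1.12,
        "bta-miR-210": 1.17,
        "bta-miR-345-5p": 1.47,
        "bta-miR-21-3p": 1.71,
    },
    "TTN_vs_HC": {
        "bta-miR-6119-3p": -1.36,
        "bta-miR-2408": -1.22,
        "bta-miR-340": -1.12,
        "bta-miR-1": 2.67,
        "bta-miR-206": 2.94,
        "bta-miR-133a": 4.32,
    },
}

# unrecovered vs recovered, per phenotype and week
RECOVERY_DE_LOG2FC: dict[tuple[str, str, str], float] = {
    ("DD", "W0", "bta-miR-1"): 3.89,
    ("FRDD", "W0", "bta-miR-2903"): -2.23,
    ("FRDD", "W0", "bta-miR-874"): -1.05,
    ("FRDD", "W0", "bta-miR-33b"): 1.58,
    ("FRDD", "W1", "bta-miR-339a"): -6.37,
    ("TTN", "W1", "bta-miR-1246"): 7.68,
    ("TTN", "W2", "bta-miR-9-5p"): 1.78,
    ("TTN", "W2", "bta-miR-296-3p"): -1.17,
    ("TTN", "W2", "bta-miR-6523a"): -1.31,
}

#: reported direction-wise averages of the W0 contrasts (precision 2);
#: the FR upregulated average is internally inconsistent in the source report
#: (printed average 1.68 vs 1.58 from the listed values) and is omitted here.
REPORTED_W0_MEANS: dict[str, dict[str, float]] = {
    "DD_vs_HC": {"down": -1.32},
    "FR_vs_HC": {"down": -1.15},
    "TTN_vs_HC": {"down": -1.23, "up": 3.31},
    "FRDD_vs_HC": {"down": -1.24, "up": 1.26},
}

#: reported direction-wise averages of the UNR-vs-RE contrasts (precision 1)
REPORTED_RECOVERY_MEANS: dict[str, float] = {"down": -2.4, "up": 3.7}
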