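"""Per-phenotype summary statistics used as synthetic-mixture presets.

The five isotope phenotypes (``a``–``e``) characterised in the White Point
sulfur-cycling biofilm SIP time course are described here by their
per-cluster ROI counts, mean ratios and standard deviations for each
incubation condition (2, 7 and 10 days of labeling, an unlabeled control
and a formaldehyde-killed control).  The synthetic module turns each block
into a five-component Gaussian mixture in ratio space.

Ratio columns
-------------
r13C    13C/12C
r15N    15N12C/14N12C
r33S    33S/32S
rC_CN   (12C + 13C) / (14N12C + 15N12C)
rS_CN   (32S + 33S + 34S) / (14N12C + 15N12C)

34S/32S is not part of the published per-cluster summaries (34S was not a
tracer); every component uses the natural-abundance VCDT value as its r34S
mean with a 10% spread (see R34S_MEAN / R34S_SD).
"""

from __future__ import annotations

CLUSTER_NAMES = ("a", "b", "c", "d", "e")

#: Ratio columns used for clustering (r34S is excluded).
CLUSTERING_RATIOS = ("r13C", "r15N", "r33S", "rC_CN", "rS_CN")

#: All ratio columns of a ratio matrix.
ALL_RATIOS = ("r13C", "r15N", "r33S", "r34S", "rC_CN", "rS_CN")

R34S_MEAN = 0.0442
R34S_SD = 0.0044

# Each block: cluster name -> (n_rois, {ratio: mean}, {ratio: sd})
PRESET_BLOCKS: dict[str, dict[str, tuple[int, dict[str, float], dict[str, float]]]] = {
    "day2": {
        "a": (253, {"r13C": 0.0625, "r15N": 0.0187, "r33S": 0.0094, "rC_CN": 0.4239, "rS_CN": 0.1084},
                   {"r13C": 0.0363, "r15N": 0.0112, "r33S": 0.0028, "rC_CN": 0.1159, "rS_CN": 0.0219}),
        "b": (107, {"r13C": 0.2284, "r15N": 0.0569, "r33S": 0.0164, "rC_CN": 0.5943, "rS_CN": 0.1415},
                   {"r13C": 0.1024, "r15N": 0.0158, "r33S": 0.0070, "rC_CN": 0.1267, "rS_CN": 0.0213}),
        "c": (257, {"r13C": 0.1889, "r15N": 0.0508, "r33S": 0.0141, "rC_CN": 0.3383, "rS_CN": 0.1028},
                   {"r13C": 0.0580, "r15N": 0.0123, "r33S": 0.0056, "rC_CN": 0.0830, "rS_CN": 0.0206}),
        "d": (30,  {"r13C": 0.1086, "r15N": 0.0370, "r33S": 0.0122, "rC_CN": 0.2667, "rS_CN": 0.2554},
                   {"r13C": 0.0486, "r15N": 0.0167, "r33S": 0.0051, "rC_CN": 0.0842, "rS_CN": 0.1106}),
        "e": (18,  {"r13C": 0.1757, "r15N": 0.0704, "r33S": 0.0622, "rC_CN": 0.3066, "rS_CN": 0.1281},
                   {"r13C": 0.0974, "r15N": 0.0259, "r33S": 0.0245, "rC_CN": 0.1191, "rS_CN": 0.0268}),
    },
    "day7": {
        "a": (443, {"r13C": 0.0304, "r15N": 0.0105, "r33S": 0.0151, "rC_CN": 0.3736, "rS_CN": 0.0886},
                   {"r13C": 0.0298, "r15N": 0.0105, "r33S": 0.0109, "rC_CN": 0.1042, "rS_CN": 0.0193}),
        "b": (136, {"r13C": 0.0499, "r15N": 0.0157, "r33S": 0.0150, "rC_CN": 0.7612, "rS_CN": 0.1509},
                   {"r13C": 0.0385, "r15N": 0.0100, "r33S": 0.0102, "rC_CN": 0.1953, "rS_CN": 0.0326}),
        "c": (106, {"r13C": 0.2687, "r15N": 0.0532, "r33S": 0.0306, "rC_CN": 0.5187, "rS_CN": 0.1188},
                   {"r13C": 0.1112, "r15N": 0.0125, "r33S": 0.0249, "rC_CN": 0.1529, "rS_CN": 0.0275}),
        "d": (32,  {"r13C": 0.0694, "r15N": 0.0217, "r33S": 0.0078, "rC_CN": 0.4769, "rS_CN": 0.3125},
                   {"r13C": 0.0397, "r15N": 0.0103, "r33S": 0.0016, "rC_CN": 0.2435, "rS_CN": 0.0815}),
        "e": (60,  {"r13C": 0.1323, "r15N": 0.1001, "r33S": 0.2229, "rC_CN": 0.2759, "rS_CN": 0.0690},
                   {"r13C": 0.0850, "r15N": 0.0162, "r33S": 0.0899, "rC_CN": 0.1203, "rS_CN": 0.0193}),
    },
    "day10": {
        "a": (306, {"r13C": 0.0655, "r15N": 0.0379, "r33S": 0.0146, "rC_CN": 0.3113, "rS_CN": 0.0648},
                   {"r13C": 0.0385, "r15N": 0.0207, "r33S": 0.0169, "rC_CN": 0.1853, "rS_CN": 0.0243}),
        # cluster b is absent at day 10 (n = 0)
        "b": (0,   {"r13C": 0.0, "r15N": 0.0, "r33S": 0.0, "rC_CN": 0.0, "rS_CN": 0.0},
                   {"r13C": 0.0, "r15N": 0.0, "r33S": 0.0, "rC_CN": 0.0, "rS_CN": 0.0}),
        "c": (158, {"r13C": 0.1943, "r15N": 0.0561, "r33S": 0.0285, "rC_CN": 0.5350, "rS_CN": 0.0650},
                   {"r13C": 0.0638, "r15N": 0.0104, "r33S": 0.0233, "rC_CN": 0.1987, "rS_CN": 0.0134}),
        "d": (66,  {"r13C": 0.0910, "r15N": 0.0448, "r33S": 0.0446, "rC_CN": 0.8700, "rS_CN": 0.1660},
                   {"r13C": 0.0452, "r15N": 0.0196, "r33S": 0.0283, "rC_CN": 0.3895, "rS_CN": 0.0905}),
        "e": (230, {"r13C": 0.0968, "r15N": 0.0739, "r33S": 0.0887, "rC_CN": 0.3907, "rS_CN": 0.0833},
                   {"r13C": 0.0307, "r15N": 0.0106, "r33S": 0.0199, "rC_CN": 0.1100, "rS_CN": 0.0213}),
    },
    "unlabeled": {
        "a": (155, {"r13C": 0.0109, "r15N": 0.0036, "r33S": 0.0074, "rC_CN": 0.3687, "rS_CN": 0.0656},
                   {"r13C": 0.0003, "r15N": 0.0001, "r33S": 0.0004, "rC_CN": 0.0891, "rS_CN": 0.0168}),
        "b": (133, {"r13C": 0.0105, "r15N": 0.0034, "r33S": 0.0074, "rC_CN": 0.4739, "rS_CN": 0.0697},
                   {"r13C": 0.0003, "r15N": 0.0001, "r33S": 0.0004, "rC_CN": 0.1442, "rS_CN": 0.0274}),
        "c": (39,  {"r13C": 0.0106, "r15N": 0.0034, "r33S": 0.0092, "rC_CN": 0.4149, "rS_CN": 0.0652},
                   {"r13C": 0.0004, "r15N": 0.0001, "r33S": 0.0009, "rC_CN": 0.1209, "rS_CN": 0.0213}),
        "d": (193, {"r13C": 0.0109, "r15N": 0.0034, "r33S": 0.0068, "rC_CN": 0.1868, "rS_CN": 0.1103},
                   {"r13C": 0.0003, "r15N": 0.0001, "r33S": 0.0003, "rC_CN": 0.0701, "rS_CN": 0.0387}),
        "e": (125, {"r13C": 0.0112, "r15N": 0.0034, "r33S": 0.0067, "rC_CN": 0.3557, "rS_CN": 0.2220},
                   {"r13C": 0.0003, "r15N": 0.0001, "r33S": 0.0002, "rC_CN": 0.1202, "rS_CN": 0.0607}),
    },
    "killed": {
        "a": (110, {"r13C": 0.0115, "r15N": 0.0046, "r33S": 0.0049, "rC_CN": 0.3165, "rS_CN": 0.0738},
                   {"r13C": 0.0015, "r15N": 0.0004, "r33S": 0.0009, "rC_CN": 0.0729, "rS_CN": 0.0137}),
        "b": (79,  {"r13C": 0.0123, "r15N": 0.0041, "r33S": 0.0063, "rC_CN": 0.1999, "rS_CN": 0.0855},
                   {"r13C": 0.0015, "r15N": 0.0003, "r33S": 0.0007, "rC_CN": 0.0935, "rS_CN": 0.0255}),
        "c": (55,  {"r13C": 0.0116, "r15N": 0.0044, "r33S": 0.0061, "rC_CN": 0.4473, "rS_CN": 0.1433},
                   {"r13C": 0.0010, "r15N": 0.0003, "r33S": 0.0008, "rC_CN": 0.1433, "rS_CN": 0.0618}),
        "d": (13,  {"r13C": 0.0120, "r15N": 0.0064, "r33S": 0.0066, "rC_CN": 0.2845, "rS_CN": 0.0684},
                   {"r13C": 0.0009, "r15N": 0.0008, "r33S": 0.0015, "rC_CN": 0.0504, "rS_CN": 0.0287}),
        "e": (11,  {"r13C": 0.0241, "r15N": 0.0048, "r33S": 0.0061, "rC_CN": 0.4123, "rS_CN": 0.0841},
                   {"r13C": 0.0060, "r15N": 0.0005, "r33S": 0.0003, "rC_CN": 0.0903, "rS_CN": 0.0225}),
    },
}

# Aliases matching the condition labels used in field notes.
PRESET_ALIASES = {"NL": "unlabeled", "K": "killed",
                  "day2": "day2", "day7": "day7", "day10": "day10",
                  "unlabeled": "unlabeled", "killed": "killed"}

#: FISH taxon composition per phenotype (probabilities over gamma/delta/unknown).
#: Phenotypes a–c are dominated by filamentous Gammaproteobacteria, d by
#: coccoidal Gammaproteobacteria, and e by Deltaproteobacteria.
DEFAULT_TAXON_MIX: dict[str, dict[str, float]] = {
    "a": {"gamma": 0.86, "delta": 0.04, "unknown": 0.10},
    "b": {"gamma": 0.98, "delta": 0.01, "unknown": 0.01},
    "c": {"gamma": 0.92, "delta": 0.04, "unknown": 0.04},
    "d": {"gamma": 0.85, "delta": 0.00, "unknown": 0.15},
    "e": {"gamma": 0.00, "delta": 0.68, "unknown": 0.32},
}

DEFAULT_MORPHOLOGY: dict[str, str] = {
    "a": "filament", "b": "filament", "c": "filament",
    "d": "coccus", "e": "rod",
}


def block_sizes(preset: str) -> dict[str, int]:
    """ROI count per phenotype for a preset block."""
    block = PRESET_BLOCKS[PRESET_ALIASES[preset]]
    return {name: block[name][0] for name in CLUSTER_NAMES}


def total_rois() -> int:
    """Total ROI count across all five preset blocks."""
    return sum(sum(block_sizes(p).values()) for p in PRESET_BLOCKS)
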