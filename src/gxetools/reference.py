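"""Published reference values from the turbot PPAR temperature experiment.

The pipeline reanalyzes a study of four peroxisome-proliferator-activated
receptor genes (PPARa1, PPARa2, PPARb, PPARg) measured by qPCR in ten
tissues of turbot (*Scophthalmus maximus*) acclimated to five temperatures
(14, 20, 23, 25, 28 degC) in three replicate blocks.  The replicate-level
measurements were distributed as a supplementary appendix and are not
bundled here; what this module freezes are the study's published summary
tables, which serve two purposes:

* arithmetic cross-checks -- every derived statistic (F ratios, percentage
  partitions, axis degrees of freedom, distances from the biplot origin)
  can be recomputed from the printed SS/df/score columns and compared to
  the printed result;
* score-based inputs -- the published GGE score triples are sufficient
  input for all rank-based biplot geometry, which is invariant to the
  singular-value partition used for plotting.

All values are transcribed exactly as printed (4-5 significant decimals).
"""

from __future__ import annotations

GENES = ["PPARa1", "PPARa2", "PPARb", "PPARg"]
TISSUES = [
    "intestine", "liver", "gill", "heart", "kidney",
    "brain", "muscle", "spleen", "skin", "stomach",
]
TEMPERATURES = ["14", "20", "23", "25", "28"]

#: Mean expression over all gene x tissue x block observations, per
#: temperature (relative units, "U/mg" in the study's convention).
GRAND_MEANS = {"14": 1.1166, "20": 1.9118, "23": 1.7727, "25": 1.9112, "28": 1.5856}

# ---------------------------------------------------------------------------
# split-split-plot ANOVA (blocks=3, temperatures=5, tissues=10, genes=4)
# rows: source -> (SS, df, MS, F or None, p or None)
# ---------------------------------------------------------------------------
SSP_ANOVA = {
    "Blocks": (1.2927, 2, 0.6464, None, None),
    "Temperature": (58.603, 4, 14.651, 18.398, 0.0004),
    "Main-plot error": (6.3707, 8, 0.7963, None, None),
    "Tissue": (270.57, 9, 30.063, 128.02, 0.0),
    "Temperature x Tissue": (328.25, 36, 9.1181, 38.83, 0.0),
    "Split-plot error": (21.134, 90, 0.2348, None, None),
    "Gene": (180.69, 3, 60.229, 249.7, 1e-7),
    "Temperature x Gene": (321.96, 12, 26.83, 111.23, 1e-7),
    "Tissue x Gene": (222.42, 27, 8.2378, 34.153, 1e-7),
    "Temperature x Tissue x Gene": (485.05, 108, 4.4912, 18.62, 1e-7),
    "Split-split-plot error": (72.361, 300, 0.2412, None, None),
}

# ---------------------------------------------------------------------------
# per-temperature AMMI decompositions (g=4 genes, e=10 tissues, r=3 blocks)
# rows: source -> (df, SS, MS, F or None, prob or None, pct or None)
# pct is % of total SS for main effects / interaction and % of interaction
# SS for the IPCA axes.
# ---------------------------------------------------------------------------
AMMI_ANOVA = {
    "14": {
        "Total": (119, 21.5253, 0.1809, None, None, None),
        "Treatment": (39, 15.2082, 0.39, 4.9384, 0.0, None),
        "Gene": (3, 0.0548, 0.0183, 0.2311, 0.87444, 0.2545),
        "Tissue": (9, 5.9496, 0.6611, 8.3718, 0.0, 27.6400),
        "Interaction": (27, 9.2039, 0.3409, 4.317, 0.0, 42.7585),
        "IPCA1": (11, 4.39599, 0.39964, 5.06101, 6e-6, 47.7622),
        "IPCA2": (9, 3.2454, 0.3606, 4.56665, 7.1e-5, 35.2611),
        "Residual": (7, 1.5625, 0.22321, None, None, None),
        "Error": (80, 6.31709, 0.07896, None, None, None),
    },
    "20": {
        "Total": (119, 480.995, 4.042, None, None, None),
        "Treatment": (39, 447.293, 11.4691, 27.2247, 0.0, None),
        "Gene": (3, 47.154, 15.718, 37.3106, 0.0, 9.8034),
        "Tissue": (9, 256.9, 28.5444, 67.7573, 0.0, 53.4100),
        "Interaction": (27, 143.239, 5.3052, 12.5931, 0.0, 29.7797),
        "IPCA1": (11, 120.236, 10.9305, 25.9463, 0.0, 83.9403),
        "IPCA2": (9, 17.053, 1.89477, 4.49772, 8.5e-5, 11.9052),
        "Residual": (7, 5.9508, 0.85011, None, None, None),
        "Error": (80, 33.702, 0.42127, None, None, None),
    },
    "23": {
        "Total": (119, 370.434, 3.1129, None, None, None),
        "Treatment": (39, 347.314, 8.9055, 30.8149, 0.0, None),
        "Gene": (3, 127.261, 42.4204, 146.784, 0.0, 34.3546),
        "Tissue": (9, 74.5141, 8.2793, 28.6483, 0.0, 20.1153),
        "Interaction": (27, 145.539, 5.3903, 18.6517, 0.0, 39.2886),
        "IPCA1": (11, 95.9195, 8.71996, 30.1729, 0.0, 65.9065),
        "IPCA2": (9, 37.9649, 4.21832, 14.5963, 0.0, 26.0857),
        "Residual": (7, 11.6543, 1.6649, None, None, None),
        "Error": (80, 23.12, 0.289, None, None, None),
    },
    "25": {
        "Total": (119, 524.157, 4.4047, None, None, None),
        "Treatment": (39, 498.347, 12.7781, 39.6067, 0.0, None),
        "Gene": (3, 195.432, 65.1441, 201.919, 0.0, 37.2850),
        "Tissue": (9, 133.402, 14.8224, 45.9432, 0.0, 25.4507),
        "Interaction": (27, 169.512, 6.2782, 19.4598, 0.0, 32.3400),
        "IPCA1": (11, 132.551, 12.0501, 37.3501, 0.0, 78.1954),
        "IPCA2": (9, 35.5725, 3.9525, 12.2511, 0.0, 20.9852),
        "Residual": (7, 1.38891, 0.19842, None, None, None),
        "Error": (80, 25.8101, 0.32263, None, None, None),
    },
    "28": {
        "Total": (119, 512.987, 4.3108, None, None, None),
        "Treatment": (39, 500.778, 12.8405, 84.1362, 0.0, None),
        "Gene": (3, 132.745, 44.2483, 289.934, 0.0, 25.8768),
        "Tissue": (9, 128.053, 14.2281, 93.229, 0.0, 24.9622),
        "Interaction": (27, 239.979, 8.8881, 58.2389, 0.0, 46.7808),
        "IPCA1": (11, 224.367, 20.397, 133.65, 0.0, 93.4943),
        "IPCA2": (9, 15.3029, 1.70032, 11.1412, 0.0, 6.3767),
        "Residual": (7, 0.30941, 0.0442, None, None, None),
        "Error": (80, 12.2092, 0.15261, None, None, None),
    },
}

# ---------------------------------------------------------------------------
# GGE score table: per temperature, label -> (PCA1, PCA2, PCA3, D_i)
# Gene rows first, then tissue rows, as published.
# ---------------------------------------------------------------------------
GGE_SCORES = {
    "14": {
        "PPARa1": (0.3631, -0.3388, 0.5799, 0.7635),
        "PPARa2": (-0.2853, -0.6881, -0.4031, 0.8470),
        "PPARb": (-0.7873, 0.5357, 0.1337, 0.9616),
        "PPARg": (0.7094, 0.4912, -0.3105, 0.9171),
        "brain": (-0.1959, -0.1842, 0.2120, 0.3424),
        "gill": (0.3742, 0.2135, 0.3533, 0.5571),
        "heart": (-0.2033, 0.0081, -0.0187, 0.2043),
        "intestine": (0.0757, -0.3207, 0.0136, 0.3298),
        "kidney": (0.1718, -0.2942, 0.1449, 0.3703),
        "liver": (-0.7228, 0.5105, -0.049, 0.8863),
        "muscle": (-0.0716, -0.5338, -0.4938, 0.7307),
        "skin": (0.2494, 0.1629, -0.0821, 0.3090),
        "spleen": (0.2178, 0.4764, -0.3899, 0.6530),
        "stomach": (0.6664, 0.2204, -0.1291, 0.7137),
    },
    "20": {
        "PPARa1": (1.0137, 0.5744, 0.8333, 1.4325),
        "PPARa2": (-0.5413, -1.2729, 0.2258, 1.4016),
        "PPARb": (-1.9714, 0.6681, -0.2492, 2.0964),
        "PPARg": (1.4990, 0.0304, -0.8098, 1.7041),
        "brain": (-0.4701, -1.0778, -0.1075, 1.1808),
        "gill": (-2.0521, -0.3423, 0.4680, 2.1324),
        "heart": (-1.7196, 0.6663, -0.5255, 1.9176),
        "intestine": (-0.1222, 0.0793, -0.0252, 0.1479),
        "kidney": (0.0731, 0.2832, 0.8371, 0.8867),
        "liver": (-0.1064, 0.7261, 0.2317, 0.7696),
        "muscle": (0.0370, 0.2154, -0.1444, 0.2620),
        "skin": (-0.1720, 0.0282, 0.0462, 0.1803),
        "spleen": (-0.0496, -0.0232, 0.3393, 0.3437),
        "stomach": (0.0133, -0.1143, -0.2517, 0.2767),
    },
    "23": {
        "PPARa1": (2.4252, -0.4588, 0.0502, 2.4687),
        "PPARa2": (-1.0131, -0.5212, -1.1106, 1.5910),
        "PPARb": (-1.2498, -0.6838, 0.9882, 1.7339),
        "PPARg": (-0.1622, 1.6639, 0.0721, 1.6734),
        "brain": (1.4789, -0.3157, 0.4705, 1.5838),
        "gill": (1.7790, -0.6510, -0.1629, 1.9014),
        "heart": (0.9966, -0.4567, 0.0363, 1.0969),
        "intestine": (0.1985, 0.0565, -0.2898, 0.3558),
        "kidney": (0.1161, -0.4054, -0.0442, 0.4240),
        "liver": (0.6440, 0.4309, -1.2183, 1.4438),
        "muscle": (1.2598, 1.2849, 0.3835, 1.8399),
        "skin": (0.1683, -0.1650, -0.4971, 0.5502),
        "spleen": (0.1445, 0.3581, 0.0620, 0.3911),
        "stomach": (0.2155, 0.9091, -0.0159, 0.9345),
    },
    "25": {
        "PPARa1": (1.9616, -1.3496, 0.1036, 2.3833),
        "PPARa2": (-1.7486, -0.1206, 0.5524, 1.8377),
        "PPARb": (-1.2483, -0.4003, -0.6314, 1.4550),
        "PPARg": (1.0353, 1.8706, -0.0247, 2.1382),
        "brain": (1.8721, -1.2646, 0.3754, 2.2902),
        "gill": (0.8757, 0.5911, 0.0162, 1.0567),
        "heart": (1.4477, -0.3709, -0.5774, 1.6021),
        "intestine": (0.3812, -0.4361, 0.1814, 0.6070),
        "kidney": (0.4074, 0.6864, -0.0198, 0.7985),
        "liver": (0.0646, 0.6955, 0.4082, 0.8091),
        "muscle": (1.2839, 0.9041, 0.0284, 1.5706),
        "skin": (0.9093, 0.4450, -0.0753, 1.0152),
        "spleen": (0.1557, 0.5520, -0.1217, 0.5864),
        "stomach": (0.5938, 0.9715, 0.1387, 1.1470),
    },
    "28": {
        "PPARa1": (2.7550, -0.2784, 0.0241, 2.7691),
        "PPARa2": (-1.2142, -0.6114, 0.3761, 1.4105),
        "PPARb": (-1.0348, -0.8981, -0.3546, 1.4154),
        "PPARg": (-0.5059, 1.7880, -0.045, 1.8588),
        "brain": (2.7607, -0.7314, 0.0951, 2.8575),
        "gill": (0.7933, 0.7247, -0.1139, 1.0805),
        "heart": (1.1408, 0.9294, -0.0646, 1.4729),
        "intestine": (0.4358, 0.2129, 0.0948, 0.4942),
        "kidney": (0.2706, 0.2908, -0.0118, 0.3974),
        "liver": (0.1054, 0.7348, 0.4034, 0.8449),
        "muscle": (0.3547, 0.1679, -0.1111, 0.4079),
        "skin": (0.6312, 0.2448, -0.1734, 0.6989),
        "spleen": (-0.1638, 1.0535, 0.0795, 1.0691),
        "stomach": (0.1145, 0.8142, -0.1518, 0.8362),
    },
}

# ---------------------------------------------------------------------------
# published gene rankings per temperature
# ---------------------------------------------------------------------------
RANKINGS = {
    "high": {
        "14": ["PPARg", "PPARa1", "PPARb", "PPARa2"],
        "20": ["PPARb", "PPARa2", "PPARa1", "PPARg"],
        "23": ["PPARa1", "PPARg", "PPARa2", "PPARb"],
        "25": ["PPARg", "PPARa1", "PPARb", "PPARa2"],
        "28": ["PPARa1", "PPARg", "PPARa2", "PPARb"],
    },
    "stable": {
        "14": ["PPARg", "PPARa1", "PPARa2", "PPARb"],
        "20": ["PPARg", "PPARb", "PPARa1", "PPARa2"],
        "23": ["PPARa2", "PPARb", "PPARa1", "PPARg"],
        "25": ["PPARb", "PPARa2", "PPARg", "PPARa1"],
        "28": ["PPARb", "PPARa2", "PPARa1", "PPARg"],
    },
    "comprehensive": {
        "14": ["PPARg", "PPARa1", "PPARa2", "PPARb"],
        "20": ["PPARb", "PPARa2", "PPARa1", "PPARg"],
        "23": ["PPARa1", "PPARg", "PPARa2", "PPARb"],
        "25": ["PPARg", "PPARa1", "PPARb", "PPARa2"],
        "28": ["PPARa1", "PPARg", "PPARa2", "PPARb"],
    },
}

#: Which-won-where partition published for the control temperature (14 degC):
#: winning gene -> tissues of its sector.
WHICH_WON_WHERE_14 = {
    "PPARg": ["spleen", "skin", "gill", "stomach"],
    "PPARa2": ["brain", "muscle", "intestine"],
    "PPARb": ["heart", "liver"],
    "PPARa1": ["kidney"],
}


def gge_result(temperature: str):
    """Published GGE score triples wrapped as a score-based result object."""
    from .gge import GgeResult

    block = GGE_SCORES[str(temperature)]
    gene_scores = [block[g][:3] for g in GENES]
    tissue_scores = [block[t][:3] for t in TISSUES]
    return GgeResult.from_scores(
        GENES, TISSUES, gene_scores, tissue_scores, temperature=str(temperature)
    )
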