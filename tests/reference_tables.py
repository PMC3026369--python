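"""Published reference predictions for the RAG tree motifs of orders 7-9.

These are the prediction values and categories reported by the original
merge-and-perceptron classification of the RAG trees: 26 classified motifs
(15 red, 11 black) and 43 unclassified order-9 motifs.  The category bands
in ``ragmerge.classify`` were reconstructed from exactly these
(value, category) pairs, so the suite checks the reconstruction against
every one of them.  Exact prediction values depend on the random weight
initialization and are not reproducible; color classes and categories are.
"""

# (rag_index, color, reported value, category)
CLASSIFIED = [
    ("7.1", "red", 1.00000, "Highly-RNA-Like"),
    ("7.2", "red", 0.99860, "Highly-RNA-Like"),
    ("7.3", "red", 0.99990, "Highly-RNA-Like"),
    ("7.6", "red", 0.99721, "Highly-RNA-Like"),
    ("7.9", "black", 0.43130, "Unclassifiable"),
    ("7.10", "black", 0.59091, "Unclassifiable"),
    ("7.11", "black", 0.00045, "Highly-Not-RNA-Like"),
    ("8.3", "red", 0.99796, "Highly-RNA-Like"),
    ("8.5", "red", 0.99991, "Highly-RNA-Like"),
    ("8.7", "red", 0.99815, "Highly-RNA-Like"),
    ("8.9", "black", 0.75935, "RNA-Like"),
    ("8.10", "red", 0.99994, "Highly-RNA-Like"),
    ("8.11", "red", 0.99682, "Highly-RNA-Like"),
    ("8.14", "black", 0.52998, "Unclassifiable"),
    ("8.15", "red", 0.56343, "Unclassifiable"),
    ("8.17", "black", 0.36524, "Not-RNA-Like"),
    ("8.18", "black", 0.00595, "Highly-Not-RNA-Like"),
    ("8.19", "black", 0.33309, "Not-RNA-Like"),
    ("8.20", "red", 0.69128, "RNA-Like"),
    ("8.21", "black", 0.00747, "Highly-Not-RNA-Like"),
    ("8.22", "black", 0.00437, "Highly-Not-RNA-Like"),
    ("8.23", "black", 0.00001, "Highly-Not-RNA-Like"),
    ("9.6", "red", 0.99991, "Highly-RNA-Like"),
    ("9.11", "red", 0.99993, "Highly-RNA-Like"),
    ("9.13", "red", 0.99740, "Highly-RNA-Like"),
    ("9.27", "red", 0.99795, "Highly-RNA-Like"),
]

# (rag_index, reported value, category) for the 43 unclassified order-9 trees
UNCLASSIFIED = [
    ("9.1", 1.00000, "Highly-RNA-Like"),
    ("9.2", 0.99888, "Highly-RNA-Like"),
    ("9.3", 0.99840, "Highly-RNA-Like"),
    ("9.4", 0.99840, "Highly-RNA-Like"),
    ("9.5", 0.72341, "RNA-Like"),
    ("9.7", 0.99875, "Highly-RNA-Like"),
    ("9.8", 0.99909, "Highly-RNA-Like"),
    ("9.9", 0.55979, "Unclassifiable"),
    ("9.10", 0.99874, "Highly-RNA-Like"),
    ("9.12", 0.99724, "Highly-RNA-Like"),
    ("9.14", 0.99722, "Highly-RNA-Like"),
    ("9.15", 0.48019, "Unclassifiable"),
    ("9.16", 0.58718, "Unclassifiable"),
    ("9.17", 0.99660, "Highly-RNA-Like"),
    ("9.18", 0.99993, "Highly-RNA-Like"),
    ("9.19", 0.81428, "Highly-RNA-Like"),
    ("9.20", 0.58342, "Unclassifiable"),
    ("9.21", 0.64473, "RNA-Like"),
    ("9.22", 0.28250, "Not-RNA-Like"),
    ("9.23", 0.84883, "Highly-RNA-Like"),
    ("9.24", 0.99705, "Highly-RNA-Like"),
    ("9.25", 0.62696, "RNA-Like"),
    ("9.26", 0.99942, "Highly-RNA-Like"),
    ("9.28", 0.36067, "Not-RNA-Like"),
    ("9.29", 0.83375, "Highly-RNA-Like"),
    ("9.30", 0.52189, "Unclassifiable"),
    ("9.31", 0.00769, "Highly-Not-RNA-Like"),
    ("9.32", 0.00464, "Highly-Not-RNA-Like"),
    ("9.33", 0.99897, "Highly-RNA-Like"),
    ("9.34", 0.81259, "Highly-RNA-Like"),
    ("9.35", 0.25818, "Not-RNA-Like"),
    ("9.36", 0.39903, "Not-RNA-Like"),
    ("9.37", 0.11790, "Highly-Not-RNA-Like"),
    ("9.38", 0.57340, "Unclassifiable"),
    ("9.39", 0.00576, "Highly-Not-RNA-Like"),
    ("9.40", 0.00238, "Highly-Not-RNA-Like"),
    ("9.41", 0.00025, "Highly-Not-RNA-Like"),
    ("9.42", 0.69128, "RNA-Like"),
    ("9.43", 0.00756, "Highly-Not-RNA-Like"),
    ("9.44", 0.40451, "Unclassifiable"),
    ("9.45", 0.00441, "Highly-Not-RNA-Like"),
    ("9.46", 0.00434, "Highly-Not-RNA-Like"),
    ("9.47", 0.00002, "Highly-Not-RNA-Like"),
]

# the worked aggregation example for tree 7.9: weight-scaled network outputs
# of its five identification classes; the tree value is sum / sum(weights)
AGGREGATION_EXAMPLE = {
    "weights": [4, 2, 1, 4, 6],
    "weighted_outputs": [
        (0.95945, 3.52754),
        (0.00030, 1.99985),
        (0.97666, 0.02253),
        (3.95652, 0.05185),
        (1.43917, 5.29130),
    ],
    "value": (0.43130, 0.64077),
}
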