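"""Published per-species unique TFBS-class counts for nine ortholog groups
of stress-associated bZIP transcription factors (rice Os, sorghum Sb,
Arabidopsis At), with the chi-square statistics printed alongside them.

Seven printed statistics are inconsistent with a plain Pearson
recomputation of the printed counts (presumably typos); they are listed
in DISCREPANT_CELLS and excluded from exact-reproduction checks.
"""

COGS = ["A1", "A2", "D1", "D2", "H1", "I1", "I2", "S1", "S2"]

UNIQUE_COUNTS = {
    "Os": [65, 45, 74, 39, 85, 70, 52, 69, 38],
    "Sb": [70, 42, 70, 48, 62, 70, 44, 62, 17],
    "At": [83, 48, 99, 91, 62, 92, 60, 81, 63],
}

ALL_SPECIES_COUNTS = [23, 12, 18, 20, 22, 23, 17, 18, 10]

# comparison key -> printed chi-square statistics per COG (3 d.p.)
PRINTED_CHISQ = {
    ("Os", "Sb", "At"): [2.357, 0.400, 6.099, 26.015, 5.061, 4.173, 2.462, 3.911, 26.927],
    ("Os", "Sb"): [0.185, 0.182, 0.111, 0.931, 3.599, 0.000, 0.667, 0.374, 8.018],
    ("Os", "At"): [2.189, 0.043, 3.613, 20.800, 3.599, 2.988, 0.571, 0.960, 6.188],
    ("Sb", "At"): [1.105, 0.400, 4.976, 13.302, 0.000, 2.988, 2.762, 2.524, 26.450],
}

#: (cog, comparison) cells whose printed value deviates from Pearson
#: recomputation by more than printed-precision rounding.
DISCREPANT_CELLS = {
    ("A1", ("Os", "Sb", "At")),
    ("D2", ("Os", "Sb", "At")),
    ("S1", ("Os", "Sb", "At")),
    ("S2", ("Os", "Sb", "At")),
    ("A2", ("Os", "Sb")),
    ("A2", ("Os", "At")),
    ("I2", ("Sb", "At")),
}

#: Reproduction tolerance: printed precision is 3 d.p., so an exact
#: recomputation may differ by up to one unit in the last digit.
TOLERANCE = 0.0015


def cells():
    """Yield (cog, comparison, counts, printed_value, consistent)."""
    for comp, values in PRINTED_CHISQ.items():
        for i, cog in enumerate(COGS):
            counts = [UNIQUE_COUNTS[sp][i] for sp in comp]
            yield cog, comp, counts, values[i], (cog, comp) not in DISCREPANT_CELLS
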