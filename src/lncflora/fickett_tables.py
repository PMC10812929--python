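"""Lookup tables for the TESTCODE statistic.

Provenance: values transcribed from Fickett, "Recognition of protein coding
regions in DNA sequences", Nucleic Acids Research 10(17):5303-5318 (1982),
Tables 1 and 2 — the same tables used by the classic coding-potential
calculators.  Each of the eight parameters (four positional asymmetries,
four base-content fractions) is binned through its threshold list and the
binned probability is combined with the parameter's weight.
"""

# Thresholds are scanned top-down; the first threshold <= the parameter value
# selects the probability at the same index.  The trailing 0.0 catches
# everything else (the lowest bin).
POSITION_THRESHOLDS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
CONTENT_THRESHOLDS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

POSITION_PROBABILITY = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}

CONTENT_PROBABILITY = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.58, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.26, 0.33, 0.26, 0.29, 0.24, 0.23, 0.32, 0.30],
}

POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
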