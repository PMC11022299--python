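"""Bundled reference benchmark counts.

Two small published-benchmark count tables ship with the package so that
metric computation can be exercised against real numbers without any
database download:

* ``FDA_BENCHMARK_CONFUSION``: per-gene confusion-matrix counts from a
  validation of a chemical-probe score database against the FDA
  drug-biomarker table, over a shared universe of 749 FDA-approved
  compounds (the counts in every row sum to 749).
* ``GOF_PROBE_COMPOSITION``: counts of gain-of-function aberrations with a
  candidate probe found in the score database, by mutation type and gene,
  from a 94-report clinical NGS cohort (75 events in total).

Only raw counts are stored; sensitivities, specificities, precisions and
percentages are always recomputed from them at run time.

One benchmark row (ESR1) prints a true-negative count one higher than the
749-drug universe allows (3+9+737+1 = 750); the counts are kept as printed,
and universe conservation fixes tn at 749 - tp - fp - fn when a conserving
matrix is required.  The rounded metrics are identical either way.
"""

from __future__ import annotations

# gene -> (tp, fp, tn, fn); every row sums to the 749-drug universe
FDA_BENCHMARK_CONFUSION: dict[str, tuple[int, int, int, int]] = {
    "CYP19A1": (3, 5, 741, 0),
    "BCR": (5, 11, 733, 0),
    "ALK": (3, 11, 734, 1),
    "EGFR": (5, 9, 735, 0),
    "BRAF": (3, 3, 743, 0),
    "ROS1": (3, 8, 738, 0),
    "ESR1": (3, 9, 737, 1),
    "KIT": (2, 13, 734, 0),
    "FGFR2": (2, 11, 736, 0),
    "ERBB2": (2, 10, 736, 1),
    "NTRK1": (2, 5, 742, 0),
    "NTRK2": (1, 9, 738, 1),
    "NTRK3": (1, 10, 737, 1),
    "FLT3": (2, 14, 733, 0),
    "PARP1": (4, 0, 745, 0),
    "RET": (1, 17, 731, 0),
    "MET": (2, 5, 742, 0),
    "RARA": (1, 5, 743, 0),
}

FDA_BENCHMARK_UNIVERSE_SIZE = 749

# (mutation_type, gene) -> event count; 75 events in total
GOF_PROBE_COMPOSITION: dict[tuple[str, str], int] = {
    ("nsSNV", "AR"): 1,
    ("nsSNV", "BRAF"): 4,
    ("nsSNV", "EED"): 1,
    ("nsSNV", "EPHA7"): 1,
    ("nsSNV", "FLT4"): 1,
    ("nsSNV", "KIT"): 1,
    ("nsSNV", "KRAS"): 19,
    ("nsSNV", "MAP2K1"): 1,
    ("nsSNV", "PIK3C2G"): 1,
    ("nsSNV", "PIK3CA"): 4,
    ("nsSNV", "RAF1"): 1,
    ("amplification", "AURKA"): 1,
    ("amplification", "CCND1"): 8,
    ("amplification", "CCND3"): 1,
    ("amplification", "CCNE1"): 4,
    ("amplification", "CDK12"): 1,
    ("amplification", "CDK4"): 2,
    ("amplification", "CDK6"): 1,
    ("amplification", "CDK8"): 1,
    ("amplification", "DNMT1"): 1,
    ("amplification", "EGFR"): 5,
    ("amplification", "ERBB2"): 4,
    ("amplification", "ERBB3"): 1,
    ("amplification", "FGFR3"): 1,
    ("amplification", "FLT3"): 1,
    ("amplification", "MDM2"): 1,
    ("amplification", "MPL"): 1,
    ("amplification", "RARA"): 1,
    ("other", "MET"): 1,
    ("fusion", "TMPRSS2-ERG"): 3,
    ("fusion", "TPM3-ROS1"): 1,
}
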