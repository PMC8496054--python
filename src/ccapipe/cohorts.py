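"""Reference cohort bookkeeping for the three CCA TMA cohorts.

These constants describe the published study populations the synthetic
generators emulate: per-cohort grading composition, the marker
positivity marginals of the nuclear/cytoplasmic cross-tabulation, and
the differential-expression gene counts of the knockdown array
experiment.  They serve as inputs for consistency checks and for
reproducing the cross-tabulation arithmetic; they are not outputs of
this package.
"""

from __future__ import annotations

__all__ = [
    "GRADE_COUNTS",
    "COHORT_SIZES",
    "POSITIVITY_MARGINALS",
    "DE_GENES_UP",
    "DE_GENES_DOWN",
    "cohort_size",
]

#: Tumor-grade composition per cohort (iCCA/pCCA/dCCA = intrahepatic,
#: perihilar, distal cholangiocarcinoma).
GRADE_COUNTS: dict[str, dict[str, int]] = {
    "iCCA": {"G1": 9, "G2": 98, "G3": 42, "G4": 3},
    "pCCA": {"G1": 8, "G2": 114, "G3": 33, "G4": 0},
    "dCCA": {"G1": 1, "G2": 84, "G3": 41, "G4": 0},
}

COHORT_SIZES: dict[str, int] = {"iCCA": 152, "pCCA": 155, "dCCA": 126}

#: Marker positivity marginals (counts of positive tumors) per cohort and
#: table row: (marker_a, marker_b, both) with marker_a = YAP, marker_b = TAZ.
POSITIVITY_MARGINALS: dict[str, dict[str, tuple[int, int, int]]] = {
    "iCCA": {
        "nuclear": (60, 48, 21),
        "cytoplasmic": (43, 4, 2),
        "nuclear_or_cytoplasmic": (68, 49, 24),
    },
    "pCCA": {
        "nuclear": (65, 55, 35),
        "cytoplasmic": (48, 3, 1),
        "nuclear_or_cytoplasmic": (76, 57, 38),
    },
    "dCCA": {
        "nuclear": (37, 83, 29),
        "cytoplasmic": (39, 6, 1),
        "nuclear_or_cytoplasmic": (55, 84, 42),
    },
}

#: Genes up-/down-regulated after combined YAP/TAZ silencing (FDR 0.05).
DE_GENES_UP = 269
DE_GENES_DOWN = 273


def cohort_size(cohort: str) -> int:
    """Cohort size recomputed from its grading subgroups."""
    return sum(GRADE_COUNTS[cohort].values())
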