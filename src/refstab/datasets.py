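"""Bundled published values from the MSC housekeeping-gene study.

Two small datasets from a published qRT-PCR stability study of five common
housekeeping candidates (*ACTB*, *EF1A*, *GAPDH*, *RPLP0*, *TBP*) in
mesenchymal stromal cells from bone marrow (BMSC), adipose tissue (ASC), and
human amniotic membrane (hAMSC), four donors per source:

- :func:`msc_group_mean_ct` — the per-source mean Ct of each candidate
  (sources × genes), used for the expression-overview ordination.
- :func:`msc_stability_values` — the per-method stability values reported
  for each of the study's seven analysis conditions (three single sources,
  three pairwise combinations, and all sources pooled), used as the golden
  input to the consensus-ranking stage.
"""

from __future__ import annotations

import pandas as pd

from .qpcr_data import ValidationError

HKGS = ("ACTB", "EF1A", "GAPDH", "RPLP0", "TBP")

#: The study's seven analysis conditions, as group-filter tuples.
CONDITIONS: dict[str, tuple[str, ...]] = {
    "BMSC": ("BMSC",),
    "ASC": ("ASC",),
    "hAMSC": ("hAMSC",),
    "BMSC/ASC": ("BMSC", "ASC"),
    "BMSC/hAMSC": ("BMSC", "hAMSC"),
    "ASC/hAMSC": ("ASC", "hAMSC"),
    "ALL": ("BMSC", "ASC", "hAMSC"),
}

_GROUP_MEAN_CT = {
    "ACTB": [12.06, 12.10, 11.53],
    "EF1A": [10.63, 10.24, 10.84],
    "GAPDH": [11.57, 11.41, 11.12],
    "RPLP0": [11.87, 11.09, 11.68],
    "TBP": [20.64, 20.67, 20.35],
}


def msc_group_mean_ct() -> pd.DataFrame:
    """Published per-source mean Ct matrix (3 sources × 5 genes)."""
    return pd.DataFrame(_GROUP_MEAN_CT, index=["BMSC", "ASC", "hAMSC"])


# Per-method stability values per condition, each method's entries listed in
# ascending (most→least stable) order; the geNorm entry starts with the
# joint best pair "A|B".
_STABILITY_VALUES: dict[str, dict[str, list[tuple[str, float]]]] = {
    "BMSC": {
        "DeltaCt": [("RPLP0", 0.30), ("EF1A", 0.31), ("ACTB", 0.40),
                    ("GAPDH", 0.44), ("TBP", 0.58)],
        "BestKeeper": [("EF1A", 0.12), ("GAPDH", 0.12), ("RPLP0", 0.16),
                       ("ACTB", 0.29), ("TBP", 0.39)],
        "NormFinder": [("EF1A", 0.08), ("RPLP0", 0.08), ("ACTB", 0.29),
                       ("GAPDH", 0.36), ("TBP", 0.55)],
        "geNorm": [("EF1A|RPLP0", 0.17), ("ACTB", 0.22), ("GAPDH", 0.29),
                   ("TBP", 0.41)],
    },
    "ASC": {
        "DeltaCt": [("EF1A", 0.33), ("TBP", 0.40), ("RPLP0", 0.41),
                    ("ACTB", 0.48), ("GAPDH", 0.66)],
        "BestKeeper": [("TBP", 0.12), ("RPLP0", 0.25), ("EF1A", 0.26),
                       ("ACTB", 0.49), ("GAPDH", 0.55)],
        "NormFinder": [("EF1A", 0.08), ("TBP", 0.20), ("RPLP0", 0.28),
                       ("ACTB", 0.36), ("GAPDH", 0.62)],
        "geNorm": [("EF1A|RPLP0", 0.17), ("TBP", 0.23), ("ACTB", 0.32),
                   ("GAPDH", 0.46)],
    },
    "hAMSC": {
        "DeltaCt": [("GAPDH", 0.50), ("TBP", 0.54), ("ACTB", 0.63),
                    ("EF1A", 0.67), ("RPLP0", 0.70)],
        "BestKeeper": [("GAPDH", 0.16), ("TBP", 0.18), ("ACTB", 0.26),
                       ("EF1A", 0.40), ("RPLP0", 0.43)],
        "NormFinder": [("GAPDH", 0.19), ("TBP", 0.34), ("EF1A", 0.54),
                       ("ACTB", 0.55), ("RPLP0", 0.59)],
        "geNorm": [("ACTB|TBP", 0.23), ("GAPDH", 0.34), ("EF1A", 0.55),
                   ("RPLP0", 0.61)],
    },
    "BMSC/ASC": {
        "DeltaCt": [("EF1A", 0.38), ("ACTB", 0.50), ("RPLP0", 0.50),
                    ("TBP", 0.54), ("GAPDH", 0.56)],
        "BestKeeper": [("EF1A", 0.23), ("TBP", 0.25), ("GAPDH", 0.37),
                       ("ACTB", 0.39), ("RPLP0", 0.39)],
        "NormFinder": [("EF1A", 0.13), ("ACTB", 0.35), ("RPLP0", 0.38),
                       ("TBP", 0.42), ("GAPDH", 0.46)],
        "geNorm": [("EF1A|RPLP0", 0.26), ("ACTB", 0.39), ("TBP", 0.45),
                   ("GAPDH", 0.49)],
    },
    "BMSC/hAMSC": {
        "DeltaCt": [("GAPDH", 0.49), ("RPLP0", 0.53), ("TBP", 0.57),
                    ("ACTB", 0.57), ("EF1A", 0.58)],
        "BestKeeper": [("GAPDH", 0.22), ("EF1A", 0.28), ("TBP", 0.28),
                       ("RPLP0", 0.32), ("ACTB", 0.39)],
        "NormFinder": [("GAPDH", 0.26), ("RPLP0", 0.36), ("TBP", 0.41),
                       ("ACTB", 0.45), ("EF1A", 0.46)],
        "geNorm": [("ACTB|GAPDH", 0.41), ("TBP", 0.47), ("RPLP0", 0.53),
                   ("EF1A", 0.55)],
    },
    "ASC/hAMSC": {
        "DeltaCt": [("TBP", 0.57), ("GAPDH", 0.64), ("EF1A", 0.66),
                    ("ACTB", 0.69), ("RPLP0", 0.69)],
        "BestKeeper": [("TBP", 0.18), ("GAPDH", 0.32), ("RPLP0", 0.38),
                       ("EF1A", 0.42), ("ACTB", 0.43)],
        "NormFinder": [("TBP", 0.30), ("GAPDH", 0.42), ("EF1A", 0.51),
                       ("ACTB", 0.56), ("RPLP0", 0.57)],
        "geNorm": [("ACTB|TBP", 0.38), ("GAPDH", 0.47), ("EF1A", 0.62),
                   ("RPLP0", 0.65)],
    },
    "ALL": {
        "DeltaCt": [("TBP", 0.57), ("EF1A", 0.57), ("GAPDH", 0.58),
                    ("RPLP0", 0.60), ("ACTB", 0.61)],
        "BestKeeper": [("TBP", 0.25), ("GAPDH", 0.33), ("EF1A", 0.34),
                       ("RPLP0", 0.40), ("ACTB", 0.42)],
        "NormFinder": [("TBP", 0.38), ("GAPDH", 0.38), ("EF1A", 0.41),
                       ("RPLP0", 0.47), ("ACTB", 0.47)],
        "geNorm": [("EF1A|RPLP0", 0.32), ("GAPDH", 0.53), ("TBP", 0.57),
                   ("ACTB", 0.59)],
    },
}

#: Published consensus geomeans (only the cleanly-determined rows; the
#: BMSC/hAMSC block hides a higher-precision BestKeeper tie and is omitted).
PUBLISHED_GEOMEANS: dict[str, dict[str, float]] = {
    "ALL": {"TBP": 1.41, "EF1A": 2.06, "GAPDH": 2.45, "RPLP0": 2.83, "ACTB": 5.00},
    "BMSC": {"EF1A": 1.19, "RPLP0": 1.57, "ACTB": 3.22, "GAPDH": 3.36, "TBP": 5.00},
    "ASC": {"EF1A": 1.32, "GAPDH": 5.00},
    "hAMSC": {"GAPDH": 1.32, "TBP": 1.68, "ACTB": 2.45, "EF1A": 3.72, "RPLP0": 5.00},
    "BMSC/ASC": {"EF1A": 1.00, "GAPDH": 4.40},
    "ASC/hAMSC": {"TBP": 1.00},
}


def msc_stability_values(condition: str) -> dict[str, list[tuple[str, float]]]:
    """Published per-method stability values for one analysis condition.

    Valid conditions: ``BMSC``, ``ASC``, ``hAMSC``, ``BMSC/ASC``,
    ``BMSC/hAMSC``, ``ASC/hAMSC``, ``ALL``.
    """
    if condition not in _STABILITY_VALUES:
        raise ValidationError(
            f"unknown condition {condition!r}; valid: {sorted(_STABILITY_VALUES)}"
        )
    return {m: list(v) for m, v in _STABILITY_VALUES[condition].items()}
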