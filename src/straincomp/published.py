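"""Published reference values for the R7 / BCP1 strain comparison.

These numbers come from the public record for *Rhodococcus opacus* R7
(accessions CP008947-CP008952) and *Rhodococcus* sp. BCP1
(AVAE01000000) and the published six-strain comparison built on them.
They are *inputs* for downstream arithmetic (genome totals, percentage
checks), not values the pipeline computes from sequence here.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd

__all__ = [
    "R7_REPLICON_LENGTHS",
    "UNIQUE_REGION_LENGTHS_BP",
    "ORDER_CONSERVATION_COUNTS",
    "SIMILARITY_BCP1_VS_R7_PCT",
    "CORE_GENOME_CDS",
    "load_category_counts",
]

# R. opacus R7: chromosome + 5 plasmids, bp
R7_REPLICON_LENGTHS: Dict[str, int] = {
    "chromosome": 8_466_345,
    "pDG1": 656_443,
    "pDG2": 426_388,
    "pDG3": 352_342,
    "pDG4": 191_359,
    "pDG5": 25_175,
}

# Total length of unique regions (bp) per strain in the six-strain comparison
UNIQUE_REGION_LENGTHS_BP: Dict[str, int] = {
    "R7": 1_145_011,
    "BCP1": 1_015_869,
    "RHA1": 1_106_630,
    "PD630": 650_025,
    "B4": 912_915,
    "SB3094": 545_841,
}

# (conserved regions, total matched regions) per ordered strain pair
ORDER_CONSERVATION_COUNTS: Dict[Tuple[str, str], Tuple[int, int]] = {
    ("BCP1", "R7"): (286, 25_919),
    ("BCP1", "RHA1"): (475, 23_532),
    ("BCP1", "PD630"): (400, 17_911),
    ("BCP1", "B4"): (481, 22_904),
    ("BCP1", "SB3094"): (642, 12_397),
    ("R7", "RHA1"): (123, 40_390),
    ("R7", "PD630"): (121, 30_862),
    ("R7", "B4"): (129, 39_122),
    ("R7", "SB3094"): (261, 21_603),
}

# Percent of BCP1 bases shared with R7 in the published comparison
SIMILARITY_BCP1_VS_R7_PCT = 81.27

# CDS clusters present in all six strains (core genome)
CORE_GENOME_CDS = 644


def load_category_counts() -> pd.DataFrame:
    """Published per-category annotation counts for R7 and BCP1."""
    ref = resources.files("straincomp.data") / "rast_category_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", index_col="category")
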