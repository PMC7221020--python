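"""Published summary counts of the reference mCRC cohort (n = 639).

These are the printed cohort-level counts of the 639-sample metastatic
colorectal cancer panel-sequencing study the default simulation spec
emulates: per-gene mutated-sample margins, the joint 2x2 counts behind the
significant pairwise associations, the side x MAP and MSI x MAP covariate
tables, and the count of mutation-free samples.  They are inputs for
reproducing the published statistics, not outputs of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import ContingencyTable2x2
from .matrix import MutationMatrix
from .panel import PANEL

REFERENCE_N = 639

#: Mutated-sample count per gene (actionable-gene table margins plus the
#: margins implied by the pairwise-association table: TP53, FBXW7, SMAD4).
REFERENCE_MARGINS: dict[str, int] = {
    "KRAS": 252,
    "TP53": 310,
    "PIK3CA": 99,
    "BRAF": 51,
    "NRAS": 31,
    "FBXW7": 43,
    "SMAD4": 29,
    "PTEN": 21,
    "MET": 6,
    "EGFR": 10,  # 11 in the pairwise table margins; both are printed
    "AKT1": 5,
    "ERBB2": 3,
    "ALK": 1,
    "MAP2K1": 1,
}

#: Samples carrying no mutation on the panel (the complement of 523/639).
REFERENCE_MUTATION_FREE = REFERENCE_N - 523


def reference_pair_tables() -> dict[tuple[str, str], ContingencyTable2x2]:
    """The 2x2 joint-status tables of the published pairwise associations.

    Rows: gene A wt/mut; columns: gene B wt/mut.  Reconstructed from the
    published per-stratum mutant counts and margins; each totals 639.
    """
    raw = {
        ("KRAS", "TP53"): (187, 200, 142, 110),
        ("KRAS", "PIK3CA"): (349, 38, 191, 61),
        ("KRAS", "BRAF"): (337, 50, 251, 1),
        ("KRAS", "NRAS"): (357, 30, 251, 1),
        ("KRAS", "FBXW7"): (367, 20, 229, 23),
        ("KRAS", "EGFR"): (384, 3, 244, 8),
        ("PIK3CA", "FBXW7"): (509, 31, 87, 12),
        ("BRAF", "SMAD4"): (565, 23, 45, 6),
        ("BRAF", "PTEN"): (570, 18, 46, 5),
        ("EGFR", "SMAD4"): (603, 26, 7, 3),
        ("TP53", "NRAS"): (320, 9, 288, 22),
    }
    return {k: ContingencyTable2x2(*v) for k, v in raw.items()}


#: Pairs whose published p-value is footnote-marked as Fisher's exact test.
REFERENCE_FISHER_PAIRS = {
    ("KRAS", "EGFR"),
    ("BRAF", "SMAD4"),
    ("BRAF", "PTEN"),
    ("EGFR", "SMAD4"),
}

#: Published direction per association: +1 co-occurrence, -1 exclusivity.
REFERENCE_DIRECTIONS: dict[tuple[str, str], int] = {
    ("KRAS", "TP53"): -1,
    ("KRAS", "PIK3CA"): +1,
    ("KRAS", "BRAF"): -1,
    ("KRAS", "NRAS"): -1,
    ("KRAS", "FBXW7"): +1,
    ("KRAS", "EGFR"): +1,
    ("PIK3CA", "FBXW7"): +1,
    ("BRAF", "SMAD4"): +1,
    ("BRAF", "PTEN"): +1,
    ("EGFR", "SMAD4"): +1,
    ("TP53", "NRAS"): +1,
    ("BRAF", "NRAS"): -1,  # stated as mutually exclusive; no printed table
}


def reference_side_by_map() -> pd.DataFrame:
    """Right/Left tumor side x MAP counts (2 x 8)."""
    from .mapping import MAP_LABELS

    return pd.DataFrame(
        [
            [12, 31, 23, 18, 36, 15, 34, 14],
            [12, 17, 15, 19, 24, 36, 3, 22],
        ],
        index=["Right", "Left"],
        columns=list(MAP_LABELS),
    )


def reference_msi_by_map() -> pd.DataFrame:
    """MSI absent/present x MAP counts for the 162 MSI-tested samples."""
    from .mapping import MAP_LABELS

    return pd.DataFrame(
        [
            [19, 31, 20, 14, 25, 24, 3, 17],
            [0, 0, 0, 0, 2, 0, 6, 1],
        ],
        index=["absent", "present"],
        columns=list(MAP_LABELS),
    )


def matrix_from_pair_table(
    t: ContingencyTable2x2, gene_a: str, gene_b: str
) -> MutationMatrix:
    """A minimal binary matrix realizing one pair's joint counts.

    All other panel genes are zero; useful for recomputing margins and
    frequencies from the published joint counts.
    """
    blocks = [
        (t.a, 0, 0),
        (t.b, 0, 1),
        (t.c, 1, 0),
        (t.d, 1, 1),
    ]
    n = t.total
    arr = np.zeros((n, len(PANEL)), dtype=np.int8)
    ia, ib = PANEL.index(gene_a), PANEL.index(gene_b)
    r = 0
    for count, sa, sb in blocks:
        arr[r : r + count, ia] = sa
        arr[r : r + count, ib] = sb
        r += count
    return MutationMatrix.from_array(arr)
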