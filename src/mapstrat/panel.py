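"""The 22-gene colon/lung hotspot panel and its fixed column order.

The panel order is frozen so that matrix columns, PCA loadings and report
rows are reproducible across runs and platforms.
"""

from __future__ import annotations

PANEL: tuple[str, ...] = (
    "KRAS", "TP53", "PIK3CA", "BRAF", "NRAS", "FBXW7", "SMAD4", "PTEN",
    "MET", "STK11", "EGFR", "CTNNB1", "AKT1", "ERBB2", "ERBB4", "FGFR1",
    "ALK", "MAP2K1", "NOTCH1", "DDR2", "FGFR3", "FGFR2",
)

#: Genes whose VUS calls exclude the whole sample from the cohort.
CORE_GENES: frozenset[str] = frozenset({"KRAS", "BRAF", "PIK3CA", "TP53"})

PANEL_INDEX: dict[str, int] = {g: i for i, g in enumerate(PANEL)}


def check_panel_gene(gene: str) -> str:
    """Return ``gene`` if it belongs to the panel, else raise ``PanelError``."""
    if gene not in PANEL_INDEX:
        from .errors import PanelError

        raise PanelError(f"{gene!r} is not a member of the 22-gene panel")
    return gene
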