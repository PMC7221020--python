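"""Assignment of samples to the eight mutational association patterns (MAPs).

The main group comes from the joint status of the two stratifier genes
(default TP53/KRAS, the pair the PCA stage selects on cohorts like the one
this package targets):

* MAP1 — stratifier-1 mutant / stratifier-2 mutant (TP53mut/KRASmut)
* MAP2 — wild-type / mutant (TP53wt/KRASmut)
* MAP3 — mutant / wild-type (TP53mut/KRASwt)
* MAP4 — wild-type / wild-type

Each group splits into ".1" (at least one mutation among the remaining
panel genes) and ".2" (none), so MAP4.2 is the mutation-free group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import rxc_association_p
from .errors import DegenerateInputError, PanelError
from .matrix import MutationMatrix, round_pct

MAP_LABELS = ("MAP1.1", "MAP1.2", "MAP2.1", "MAP2.2", "MAP3.1", "MAP3.2", "MAP4.1", "MAP4.2")

DEFAULT_STRATIFIERS = ("TP53", "KRAS")


@dataclass
class MapAssignment:
    labels: pd.Series  # sample_id -> MAP label
    stratifiers: tuple[str, str]

    @property
    def n_samples(self) -> int:
        return len(self.labels)


def assign_map(
    row: pd.Series, stratifiers: tuple[str, str] = DEFAULT_STRATIFIERS
) -> str:
    """MAP label for one sample's binary gene-status vector."""
    g1, g2 = stratifiers
    if g1 == g2:
        raise ValueError("stratifier genes must be distinct")
    for g in stratifiers:
        if g not in row.index:
            raise PanelError(f"stratifier {g!r} missing from status vector")
    vals = row.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("gene status vector must be binary")
    s1, s2 = int(row[g1]), int(row[g2])
    main = {(1, 1): 1, (0, 1): 2, (1, 0): 3, (0, 0): 4}[(s1, s2)]
    others = int(row.drop(list(stratifiers)).sum())
    sub = 1 if others >= 1 else 2
    return f"MAP{main}.{sub}"


def assign_cohort(
    m: MutationMatrix, stratifiers: tuple[str, str] = DEFAULT_STRATIFIERS
) -> MapAssignment:
    """Vectorized MAP assignment of a whole matrix (a partition of samples)."""
    g1, g2 = stratifiers
    if g1 == g2:
        raise ValueError("stratifier genes must be distinct")
    for g in stratifiers:
        if g not in m.df.columns:
            raise PanelError(f"stratifier {g!r} not in matrix")
    s1 = m.df[g1].to_numpy()
    s2 = m.df[g2].to_numpy()
    main = np.select(
        [(s1 == 1) & (s2 == 1), (s1 == 0) & (s2 == 1), (s1 == 1) & (s2 == 0)],
        [1, 2, 3],
        default=4,
    )
    others = m.df.drop(columns=list(stratifiers)).to_numpy().sum(axis=1)
    sub = np.where(others >= 1, 1, 2)
    labels = pd.Series(
        [f"MAP{a}.{b}" for a, b in zip(main, sub)], index=m.df.index, name="map"
    )
    return MapAssignment(labels=labels, stratifiers=(g1, g2))


def map_composition(a: MapAssignment) -> pd.DataFrame:
    """Counts and percentages per MAP (all eight labels, zeros kept)."""
    if a.n_samples == 0:
        raise DegenerateInputError("composition undefined for an empty cohort")
    counts = a.labels.value_counts().reindex(MAP_LABELS, fill_value=0)
    pct = [round_pct(100.0 * c / a.n_samples) for c in counts]
    return pd.DataFrame({"count": counts.astype(int), "pct": pct}, index=MAP_LABELS)


def per_map_gene_frequency(
    m: MutationMatrix, a: MapAssignment, genes: list[str] | None = None
) -> pd.DataFrame:
    """MAP x gene percentage table (NaN marks an empty MAP, not 0)."""
    if not m.df.index.equals(a.labels.index):
        raise DegenerateInputError("assignment and matrix must share samples")
    if genes is None:
        genes = [g for g in m.genes if g not in a.stratifiers]
    out = pd.DataFrame(np.nan, index=list(MAP_LABELS), columns=genes, dtype=float)
    for lab in MAP_LABELS:
        members = a.labels.index[a.labels == lab]
        if len(members) == 0:
            continue  # undefined, stays NaN
        sub = m.df.loc[members, genes]
        out.loc[lab] = [round_pct(100.0 * sub[g].sum() / len(members)) for g in genes]
    return out


def compare_gene_across_maps(
    m: MutationMatrix,
    a: MapAssignment,
    gene: str,
    method: str = "auto",
    b: int = 100_000,
    seed: int | None = 0,
) -> float:
    """p-value of an r x 2 test of one gene's status across non-empty MAPs."""
    if gene not in m.df.columns:
        raise PanelError(f"{gene!r} not in matrix")
    groups = [lab for lab in MAP_LABELS if (a.labels == lab).any()]
    if len(groups) < 2:
        raise DegenerateInputError("need >=2 non-empty MAP groups")
    table = np.zeros((len(groups), 2), dtype=np.int64)
    for i, lab in enumerate(groups):
        members = a.labels == lab
        status = m.df.loc[members.to_numpy(), gene]
        table[i] = [(status == 0).sum(), (status == 1).sum()]
    p, _ = rxc_association_p(table, method=method, b=b, seed=seed)
    return p


def load_therapy_lookup(path: str | Path | None = None) -> dict[str, list[str]]:
    if path is None:
        from importlib.resources import files

        text = files("mapstrat.data").joinpath("therapy_notes.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def therapy_notes(label: str, lookup: dict[str, list[str]] | None = None) -> list[str]:
    """Configured therapeutic annotation strings for one MAP label."""
    if lookup is None:
        lookup = load_therapy_lookup()
    if label not in lookup:
        warnings.warn(f"no therapy notes configured for {label!r}", stacklevel=2)
        return []
    return list(lookup[label])
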