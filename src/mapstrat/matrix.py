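"""The binary sample x gene mutation matrix and cohort-level summaries.

The matrix entry ``M[i, j]`` is 1 when sample ``i`` carries at least one
retained mutation in gene ``j``.  Samples with no retained mutation at all
stay in the matrix as all-zero rows: a mutation-free sample is still a
cohort member (and gets its own stratification group downstream).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .curation import CurationResult
from .errors import ConsistencyError, DegenerateInputError, PanelError
from .panel import PANEL


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round half-up, the convention of clinical report tables."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class MutationMatrix:
    """Samples (rows) x panel genes (columns), entries strictly 0/1."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")
        if self.df.index.has_duplicates or self.df.columns.has_duplicates:
            raise ValueError("sample and gene labels must be unique")
        self.df = self.df.astype(np.int8)

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def genes(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        samples: Sequence[str] | None = None,
        genes: Sequence[str] = PANEL,
    ) -> "MutationMatrix":
        if samples is None:
            samples = [f"S{i:05d}" for i in range(arr.shape[0])]
        return cls(pd.DataFrame(arr, index=list(samples), columns=list(genes)))


def build_matrix(
    curation: CurationResult,
    samples: Sequence[str],
    panel: Sequence[str] = PANEL,
) -> MutationMatrix:
    """Collapse retained calls into the binary matrix over ``samples``.

    ``samples`` must cover every sample with retained calls and contain no
    excluded sample; samples without calls become all-zero rows.
    """
    sample_set = set(samples)
    missing = curation.retained_samples - sample_set
    if missing:
        raise ConsistencyError(
            f"samples with retained calls missing from sample list: {sorted(missing)[:5]}"
        )
    leaked = sample_set & curation.excluded_samples
    if leaked:
        raise ConsistencyError(
            f"excluded samples present in sample list: {sorted(leaked)[:5]}"
        )
    df = pd.DataFrame(0, index=list(samples), columns=list(panel), dtype=np.int8)
    for (sample, gene) in curation.retained_calls:
        if gene not in df.columns:
            raise PanelError(f"retained call in gene {gene!r} outside requested panel")
        df.loc[sample, gene] = 1
    return MutationMatrix(df)


def mutation_frequencies(m: MutationMatrix) -> pd.DataFrame:
    """Per-gene mutated-sample counts and percentages (one decimal)."""
    if m.n_samples == 0:
        raise DegenerateInputError("mutation frequencies undefined for zero samples")
    counts = m.df.sum(axis=0)
    pct = [round_pct(100.0 * c / m.n_samples) for c in counts]
    return pd.DataFrame({"count": counts.astype(int), "pct": pct}, index=m.genes)


def comutation_table(m: MutationMatrix, gene: str) -> dict[str, int]:
    """Co-mutation summary for one index gene.

    Counts samples wild-type / mutant for ``gene``, and within each stratum
    how many carry at least one mutation in any *other* gene.
    """
    if gene not in m.df.columns:
        raise PanelError(f"{gene!r} not in matrix")
    status = m.df[gene].to_numpy().astype(bool)
    others = m.df.drop(columns=gene).to_numpy().any(axis=1) if m.df.shape[1] > 1 else np.zeros(
        m.n_samples, dtype=bool
    )
    return {
        "wt_count": int((~status).sum()),
        "mut_count": int(status.sum()),
        "wt_with_additional": int((~status & others).sum()),
        "mut_with_additional": int((status & others).sum()),
    }


@dataclass(frozen=True)
class ActionabilityConfig:
    """Which genes/variants count as actionable, with a druggable flag.

    ``criteria`` maps gene -> either the string "any" (any retained
    mutation) or a list of protein changes; ``druggable`` flags the subset
    with an approved or investigational drug match.
    """

    criteria: Mapping[str, object] = field(default_factory=dict)
    druggable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.criteria) - set(PANEL)
        if bad:
            raise PanelError(f"actionability config references non-panel genes {sorted(bad)}")


def load_actionability(path: str | Path | None = None) -> ActionabilityConfig:
    if path is None:
        from importlib.resources import files

        text = files("mapstrat.data").joinpath("actionability.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return ActionabilityConfig(
        criteria=doc["criteria"], druggable=frozenset(doc.get("druggable", ()))
    )


def actionable_summary(m: MutationMatrix, cfg: ActionabilityConfig) -> dict:
    """Cohort actionability: samples with >=1 actionable mutation, and the
    per-gene "exclusively this gene" breakdown."""
    if not cfg.criteria:
        raise ValueError("actionability config is empty")
    genes = [g for g in cfg.criteria if g in m.df.columns]
    hits = m.df[genes].to_numpy().astype(bool)  # variant whitelists collapse to gene level
    any_actionable = hits.any(axis=1)
    all_mut = m.df.to_numpy().astype(bool)
    n_total_mut = all_mut.sum(axis=1)
    exclusive = {}
    for k, g in enumerate(genes):
        gi = m.genes.index(g)
        only = all_mut[:, gi] & (n_total_mut == 1)
        exclusive[g] = int(only.sum())
    druggable_genes = [g for g in genes if g in cfg.druggable]
    n_druggable = (
        int(m.df[druggable_genes].to_numpy().astype(bool).any(axis=1).sum())
        if druggable_genes
        else 0
    )
    n_act = int(any_actionable.sum())
    return {
        "n_samples": m.n_samples,
        "n_actionable": n_act,
        "pct_actionable": round_pct(100.0 * n_act / m.n_samples) if m.n_samples else 0.0,
        "n_druggable": n_druggable,
        "exclusively_one_gene": exclusive,
    }
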