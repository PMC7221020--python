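"""Clinical-relevance curation of raw panel variant calls.

Raw calls from hotspot panel sequencing are noisy: they mix low-quality
calls, benign polymorphisms, established hotspot mutations and variants of
unknown significance (VUS).  This module applies per-gene clinical-relevance
rules to keep only calls of established relevance:

* a caller-quality floor (default 30) applied before any biological rule;
* KRAS retained only at the activating codons 12/13/59/61/117/146;
* BRAF retained only for V600E;
* PIK3CA retained only in the two hotspot exons (default 10 and 21, the
  numbering of the panel's reference transcripts; configurable);
* TP53 retained when labelled pathogenic/likely-pathogenic or when hitting a
  configurable hotspot-codon list (an offline stand-in for a ClinVar query);
* every other panel gene retained on a pathogenic / likely-pathogenic /
  predicted-deleterious label.

A VUS in one of the four core genes (KRAS, BRAF, PIK3CA, TP53) disqualifies
the whole sample from the cohort; VUS in other genes are simply dropped.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import CurationConflictError, PanelError, ParseError
from .panel import CORE_GENES, PANEL, PANEL_INDEX

logger = logging.getLogger(__name__)

DELETERIOUS_LABELS = frozenset({"pathogenic", "likely_pathogenic", "predicted_deleterious"})
VALID_LABELS = DELETERIOUS_LABELS | {"benign", "vus", "unannotated"}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "TER": "*", "SEC": "U",
}

_PCHANGE_RE = re.compile(
    r"^(?:p\.)?\(?\s*([A-Za-z]{1,3}|\*)\s*(\d+)\s*([A-Za-z0-9_*>=.?]*)\)?$"
)


class Decision(enum.Enum):
    """Outcome of curating one variant record."""

    RETAIN = "retain"
    DISCARD_QUALITY = "discard_quality"
    DISCARD_BENIGN = "discard_benign"
    VUS = "vus"


@dataclass(frozen=True)
class VariantRecord:
    """One raw variant call on one sample/gene.

    ``codon`` and ``exon`` may be absent (None); the codon can often be
    recovered from ``protein_change``.  ``pathogenicity_label`` is the
    verdict consumed as input (ClinVar / in-silico predictors upstream).
    """

    sample_id: str
    gene: str
    protein_change: str = ""
    codon: int | None = None
    exon: int | None = None
    quality: float = 0.0
    pathogenicity_label: str = "unannotated"
    transcript: str = ""

    def __post_init__(self) -> None:
        if self.gene not in PANEL_INDEX:
            raise PanelError(f"{self.gene!r} is not a member of the 22-gene panel")
        if not self.sample_id:
            raise ValueError("sample_id must be a non-empty string")
        if self.quality < 0:
            raise ValueError(f"quality must be >= 0, got {self.quality}")
        if self.codon is not None and self.codon < 1:
            raise ValueError(f"codon must be >= 1, got {self.codon}")
        if self.exon is not None and self.exon < 1:
            raise ValueError(f"exon must be >= 1, got {self.exon}")
        if self.pathogenicity_label not in VALID_LABELS:
            raise ValueError(
                f"unknown pathogenicity label {self.pathogenicity_label!r}; "
                f"expected one of {sorted(VALID_LABELS)}"
            )


def normalize_protein_change(pchange: str) -> str:
    """Canonical one-letter, ``p.``-less form of an HGVS-p style string.

    Accepts "p.G12D", "G12D", "p.Gly12Asp", "p.(Gly12Asp)"; returns "G12D".
    Unparseable strings are returned stripped but otherwise untouched.
    """
    s = pchange.strip()
    m = _PCHANGE_RE.match(s)
    if not m:
        return s
    ref, pos, rest = m.groups()
    ref = _AA3_TO_1.get(ref.upper(), ref.upper() if len(ref) == 1 else ref)
    tail = _AA3_TO_1.get(rest.upper(), rest)
    if len(rest) == 3 and rest.upper() in _AA3_TO_1:
        tail = _AA3_TO_1[rest.upper()]
    return f"{ref}{pos}{tail}"


def parse_codon(pchange: str) -> int | None:
    """Extract the codon number from a protein-change string, if any."""
    m = _PCHANGE_RE.match(pchange.strip())
    if not m:
        return None
    return int(m.group(2))


@dataclass(frozen=True)
class GeneRule:
    """Clinical-relevance rule for one gene.

    A record is retained when it matches *any* enabled criterion.  A rule
    with only ``accepted_labels`` is a pure label-based rule.
    """

    codon_whitelist: frozenset[int] = frozenset()
    exact_variant_whitelist: frozenset[str] = frozenset()
    exon_whitelist: frozenset[int] = frozenset()
    accepted_labels: frozenset[str] = frozenset()
    hotspot_codons: frozenset[int] = frozenset()

    def matches(self, record: VariantRecord) -> bool:
        if self.accepted_labels and record.pathogenicity_label in self.accepted_labels:
            return True
        if self.exact_variant_whitelist:
            norm = normalize_protein_change(record.protein_change)
            wl = {normalize_protein_change(v) for v in self.exact_variant_whitelist}
            if not norm and record.protein_change:
                raise ParseError(f"cannot parse protein change in {record!r}")
            if norm in wl:
                return True
        for codons in (self.codon_whitelist, self.hotspot_codons):
            if codons:
                codon = record.codon
                if codon is None:
                    if not record.protein_change:
                        raise ParseError(
                            f"codon rule needs a codon or parseable protein change: {record!r}"
                        )
                    codon = parse_codon(record.protein_change)
                    if codon is None:
                        raise ParseError(
                            f"cannot extract codon from {record.protein_change!r} "
                            f"({record.sample_id}/{record.gene})"
                        )
                if codon in codons:
                    return True
        if self.exon_whitelist and record.exon is not None and record.exon in self.exon_whitelist:
            return True
        return False


@dataclass(frozen=True)
class CurationRuleSet:
    quality_threshold: float = 30.0
    rules: Mapping[str, GeneRule] = field(default_factory=dict)
    core_genes: frozenset[str] = CORE_GENES

    def __post_init__(self) -> None:
        if self.quality_threshold <= 0:
            raise ValueError("quality_threshold must be > 0")
        for g in self.rules:
            if g not in PANEL_INDEX:
                raise PanelError(f"rule references non-panel gene {g!r}")
        if not self.core_genes <= set(PANEL):
            raise PanelError(f"core genes outside panel: {set(self.core_genes) - set(PANEL)}")


def classify_variant(record: VariantRecord, rules: CurationRuleSet) -> Decision:
    """Apply the rule table to a single record.

    Quality is checked first, then the benign label, then the gene rule.
    Records failing the gene rule with a non-benign label become VUS.
    """
    if record.gene not in rules.rules:
        raise PanelError(f"no curation rule covers gene {record.gene!r}")
    if record.quality < rules.quality_threshold:
        return Decision.DISCARD_QUALITY
    if record.pathogenicity_label == "benign":
        return Decision.DISCARD_BENIGN
    if rules.rules[record.gene].matches(record):
        return Decision.RETAIN
    return Decision.VUS


@dataclass
class CurationResult:
    """Outcome of curating a cohort of records.

    ``retained_calls`` maps (sample_id, gene) to the supporting records;
    ``decisions`` is parallel to the input record list; ``excluded_samples``
    are samples disqualified by a core-gene VUS.
    """

    retained_calls: dict[tuple[str, str], list[VariantRecord]]
    decisions: list[Decision]
    excluded_samples: set[str]

    @property
    def retained_samples(self) -> set[str]:
        return {s for s, _ in self.retained_calls}


def _check_label_conflicts(records: Sequence[VariantRecord]) -> None:
    seen: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in records:
        if r.protein_change:
            seen[(r.gene, normalize_protein_change(r.protein_change))].add(
                r.pathogenicity_label
            )
    conflicts = {k: v for k, v in seen.items() if len(v) > 1}
    if conflicts:
        msg = "; ".join(f"{g} {p}: {sorted(v)}" for (g, p), v in sorted(conflicts.items()))
        raise CurationConflictError(f"conflicting pathogenicity labels: {msg}")


def curate_cohort(
    records: Sequence[VariantRecord], rules: CurationRuleSet
) -> CurationResult:
    """Curate every record, then drop samples with core-gene VUS.

    Duplicate identical records are tolerated (logged and deduplicated in
    ``retained_calls``); the same variant string with conflicting labels is
    an error.
    """
    _check_label_conflicts(records)
    n_dups = len(records) - len(set(records))
    if n_dups:
        logger.info("deduplicating %d identical variant records", n_dups)

    decisions = [classify_variant(r, rules) for r in records]
    excluded = {
        r.sample_id
        for r, d in zip(records, decisions)
        if d is Decision.VUS and r.gene in rules.core_genes
    }
    retained: dict[tuple[str, str], list[VariantRecord]] = defaultdict(list)
    for r, d in zip(records, decisions):
        if d is Decision.RETAIN and r.sample_id not in excluded:
            key = (r.sample_id, r.gene)
            if r not in retained[key]:
                retained[key].append(r)
    return CurationResult(dict(retained), decisions, excluded)


# ---------------------------------------------------------------------------
# rule-set / variant-table IO

def _rule_from_dict(d: Mapping) -> GeneRule:
    return GeneRule(
        codon_whitelist=frozenset(d.get("codon_whitelist", ())),
        exact_variant_whitelist=frozenset(d.get("exact_variant_whitelist", ())),
        exon_whitelist=frozenset(d.get("exon_whitelist", ())),
        accepted_labels=frozenset(d.get("accepted_labels", ())),
        hotspot_codons=frozenset(d.get("hotspot_codons", ())),
    )


def load_rules(path: str | Path | None = None) -> CurationRuleSet:
    """Load a rule set from YAML; with no path, the packaged default rules."""
    if path is None:
        from importlib.resources import files

        text = files("mapstrat.data").joinpath("default_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return CurationRuleSet(
        quality_threshold=float(doc.get("quality_threshold", 30)),
        rules={g: _rule_from_dict(r or {}) for g, r in doc["genes"].items()},
        core_genes=frozenset(doc.get("core_genes", sorted(CORE_GENES))),
    )


_TSV_COLUMNS = [
    "sample_id", "gene", "protein_change", "codon", "exon",
    "quality", "pathogenicity_label", "transcript",
]


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a minimal MAF-dialect tab-separated variant table."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_TSV_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        def get(name, default=None):
            v = getattr(row, name, default)
            return default if pd.isna(v) else v

        records.append(
            VariantRecord(
                sample_id=str(get("sample_id")),
                gene=str(get("gene")),
                protein_change=str(get("protein_change", "") or ""),
                codon=None if get("codon") is None else int(get("codon")),
                exon=None if get("exon") is None else int(get("exon")),
                quality=float(get("quality", 0.0) or 0.0),
                pathogenicity_label=str(get("pathogenicity_label", "unannotated")),
                transcript=str(get("transcript", "") or ""),
            )
        )
    return records


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
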