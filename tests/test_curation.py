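"""Clinical-relevance curation: rule table, sample exclusion, properties."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapstrat import (
    Decision,
    VariantRecord,
    classify_variant,
    curate_cohort,
)
from mapstrat.curation import (
    CurationRuleSet,
    normalize_protein_change,
    parse_codon,
)
from mapstrat.errors import CurationConflictError, PanelError


def rec(**kw):
    base = dict(
        sample_id="S1",
        gene="KRAS",
        protein_change="p.G12D",
        codon=12,
        exon=2,
        quality=250.0,
        pathogenicity_label="unannotated",
    )
    base.update(kw)
    return VariantRecord(**base)


@pytest.mark.parametrize(
    "record_kw, expected",
    [
        # KRAS activating-codon whitelist
        (dict(gene="KRAS", protein_change="p.G12D", codon=12, quality=250), Decision.RETAIN),
        (dict(gene="KRAS", protein_change="p.A146T", codon=146), Decision.RETAIN),
        (dict(gene="KRAS", protein_change="p.L19F", codon=19), Decision.VUS),
        # codon recovered from the protein change when the field is absent
        (dict(gene="KRAS", protein_change="G13D", codon=None), Decision.RETAIN),
        (dict(gene="KRAS", protein_change="p.Gly12Asp", codon=None), Decision.RETAIN),
        # BRAF: only V600E
        (dict(gene="BRAF", protein_change="p.V600E", codon=600), Decision.RETAIN),
        (dict(gene="BRAF", protein_change="p.D594G", codon=594, quality=200), Decision.VUS),
        # PIK3CA hotspot exons
        (dict(gene="PIK3CA", protein_change="p.E545K", codon=545, exon=10), Decision.RETAIN),
        (dict(gene="PIK3CA", protein_change="p.R88Q", codon=88, exon=2), Decision.VUS),
        # TP53: pathogenic label or hotspot codon
        (dict(gene="TP53", protein_change="p.V143A", codon=143,
              pathogenicity_label="pathogenic"), Decision.RETAIN),
        (dict(gene="TP53", protein_change="p.R273H", codon=273), Decision.RETAIN),
        (dict(gene="TP53", protein_change="p.S99F", codon=99), Decision.VUS),
        (dict(gene="TP53", protein_change="p.P72R", codon=72,
              pathogenicity_label="benign"), Decision.DISCARD_BENIGN),
        # non-core genes: label-based
        (dict(gene="NRAS", protein_change="p.Q61K", codon=61,
              pathogenicity_label="pathogenic"), Decision.RETAIN),
        (dict(gene="PTEN", protein_change="p.R130Q", codon=130,
              pathogenicity_label="predicted_deleterious"), Decision.RETAIN),
        (dict(gene="PTEN", protein_change="p.A79T", codon=79,
              pathogenicity_label="unannotated"), Decision.VUS),
        # quality floor wins over everything
        (dict(gene="KRAS", protein_change="p.G12D", codon=12, quality=29), Decision.DISCARD_QUALITY),
        (dict(gene="TP53", protein_change="p.R273H", codon=273, quality=0), Decision.DISCARD_QUALITY),
    ],
)
def test_classify_variant_rule_table(rules, record_kw, expected):
    assert classify_variant(rec(**record_kw), rules) is expected


def test_quality_checked_before_benign(rules):
    r = rec(gene="TP53", pathogenicity_label="benign", quality=10)
    assert classify_variant(r, rules) is Decision.DISCARD_QUALITY


def test_unknown_gene_rejected_at_construction():
    with pytest.raises(PanelError):
        rec(gene="MYC")


def test_missing_rule_raises(rules):
    partial = CurationRuleSet(rules=dict(list(rules.rules.items())[:1]))
    with pytest.raises(PanelError):
        classify_variant(rec(gene="TP53"), partial)


def test_core_gene_vus_excludes_sample(rules):
    records = [rec(sample_id=f"S{i}", gene="KRAS", codon=12) for i in range(4)]
    records.append(rec(sample_id="S9", gene="TP53", protein_change="p.S99F", codon=99))
    result = curate_cohort(records, rules)
    assert result.excluded_samples == {"S9"}
    assert result.retained_samples == {"S0", "S1", "S2", "S3"}
    # the excluded sample contributes no retained calls
    assert all(s != "S9" for s, _ in result.retained_calls)


def test_noncore_vus_is_dropped_not_excluding(rules):
    records = [
        rec(sample_id="S1", gene="KRAS", codon=12),
        rec(sample_id="S1", gene="PTEN", protein_change="p.A79T", codon=79,
            pathogenicity_label="unannotated"),
    ]
    result = curate_cohort(records, rules)
    assert result.excluded_samples == set()
    assert set(result.retained_calls) == {("S1", "KRAS")}


def test_empty_cohort(rules):
    result = curate_cohort([], rules)
    assert result.retained_calls == {} and result.excluded_samples == set()


def test_duplicates_tolerated_conflicts_rejected(rules):
    r = rec(sample_id="S1")
    result = curate_cohort([r, r], rules)
    assert result.retained_calls[("S1", "KRAS")] == [r]
    with pytest.raises(CurationConflictError):
        curate_cohort(
            [r, dataclasses.replace(r, pathogenicity_label="benign")], rules
        )


# --- randomized comparison against an independent per-record oracle --------

def _oracle_decision(r, rules):
    """Literal restatement of the rule table, independent of GeneRule."""
    if r.quality < rules.quality_threshold:
        return Decision.DISCARD_QUALITY
    if r.pathogenicity_label == "benign":
        return Decision.DISCARD_BENIGN
    codon = r.codon if r.codon is not None else parse_codon(r.protein_change)
    if r.gene == "KRAS":
        ok = codon in {12, 13, 59, 61, 117, 146}
    elif r.gene == "BRAF":
        ok = normalize_protein_change(r.protein_change) == "V600E"
    elif r.gene == "PIK3CA":
        ok = r.exon in {10, 21}
    elif r.gene == "TP53":
        ok = r.pathogenicity_label in {"pathogenic", "likely_pathogenic"} or codon in {
            175, 176, 179, 196, 213, 220, 245, 248, 249, 273, 282
        }
    else:
        ok = r.pathogenicity_label in {
            "pathogenic", "likely_pathogenic", "predicted_deleterious"
        }
    return Decision.RETAIN if ok else Decision.VUS


def test_randomized_cohort_matches_bruteforce_oracle(rules, rng):
    from mapstrat.simulate import DEFAULT_HOTSPOTS, DEFAULT_VUS_VARIANTS

    pool = []
    for gene, variants in DEFAULT_HOTSPOTS.items():
        pool.extend((gene, v) for v in variants)
    for gene, v in DEFAULT_VUS_VARIANTS.items():
        pool.append((gene, v))
    records = []
    for i in range(50):
        gene, v = pool[rng.integers(len(pool))]
        records.append(
            VariantRecord(
                sample_id=f"S{rng.integers(12)}",
                gene=gene,
                protein_change=v.protein_change,
                codon=v.codon,
                exon=v.exon,
                quality=float(rng.choice([10, 29, 30, 400])),
                pathogenicity_label=v.label,
            )
        )
    result = curate_cohort(records, rules)
    oracle = [_oracle_decision(r, rules) for r in records]
    assert result.decisions == oracle
    excluded = {
        r.sample_id
        for r, d in zip(records, oracle)
        if d is Decision.VUS and r.gene in rules.core_genes
    }
    assert result.excluded_samples == excluded
    retained = {
        (r.sample_id, r.gene)
        for r, d in zip(records, oracle)
        if d is Decision.RETAIN and r.sample_id not in excluded
    }
    assert set(result.retained_calls) == retained


# --- invariants -------------------------------------------------------------

@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    quality=st.floats(min_value=0, max_value=500),
    label=st.sampled_from(
        ["pathogenic", "likely_pathogenic", "predicted_deleterious", "benign",
         "vus", "unannotated"]
    ),
    gene=st.sampled_from(["KRAS", "TP53", "NRAS", "PTEN"]),
    codon=st.integers(min_value=1, max_value=300),
)
def test_every_record_gets_exactly_one_decision(quality, label, gene, codon):
    rules = load_rules_cached()
    r = VariantRecord(
        sample_id="S", gene=gene, protein_change=f"p.A{codon}T", codon=codon,
        quality=quality, pathogenicity_label=label,
    )
    d = classify_variant(r, rules)
    assert d in Decision


def load_rules_cached(_cache={}):
    if "r" not in _cache:
        from mapstrat import load_rules

        _cache["r"] = load_rules()
    return _cache["r"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(threshold=st.floats(min_value=1, max_value=600))
def test_raising_quality_threshold_shrinks_retained_set(threshold):
    import dataclasses as dc

    rules = load_rules_cached()
    records = [
        VariantRecord(
            sample_id=f"S{i}", gene="KRAS", protein_change="p.G12D", codon=12,
            quality=float(q),
        )
        for i, q in enumerate([5, 40, 100, 350, 599])
    ]
    lo = curate_cohort(records, rules)
    hi = curate_cohort(records, dc.replace(rules, quality_threshold=max(threshold, 30.0)))
    assert set(hi.retained_calls) <= set(lo.retained_calls)


def test_curation_idempotent_on_retained_output(rules, rng):
    from mapstrat.simulate import CohortSpec, simulate_profiles, simulate_variant_records

    spec = CohortSpec.paper_default(n_samples=60, seed=5)
    m = simulate_profiles(spec)
    sim = simulate_variant_records(m, spec)
    first = curate_cohort(sim.records, rules)
    retained_records = [r for recs in first.retained_calls.values() for r in recs]
    second = curate_cohort(retained_records, rules)
    assert set(second.retained_calls) == set(first.retained_calls)
    assert second.excluded_samples == set()
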