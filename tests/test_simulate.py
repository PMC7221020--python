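"""Latent-Gaussian-copula cohort generator: calibration and recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import integrate, stats

from mapstrat import (
    AssociationSpec,
    CohortSpec,
    calibrate_latent_correlation,
    curate_cohort,
    build_matrix,
    load_rules,
    recovery_report,
    simulate_covariates,
    simulate_profiles,
    simulate_variant_records,
)
from mapstrat.association import contingency_2x2, odds_ratio
from mapstrat.errors import FeasibilityError
from mapstrat.simulate import bvn_rectangle_prob, build_latent_correlation


# --- bivariate-normal rectangle probability ---------------------------------

def dblquad_oracle(z1, z2, rho):
    """Independent numerical double integral of the bivariate normal."""
    def pdf(y, x):
        det = 1 - rho**2
        q = (x * x - 2 * rho * x * y + y * y) / det
        return np.exp(-q / 2) / (2 * np.pi * np.sqrt(det))

    val, _ = integrate.dblquad(pdf, z1, 8.0, z2, 8.0, epsabs=1e-11)
    return val


@pytest.mark.parametrize(
    "z1,z2,rho",
    [(0.0, 0.0, 0.5), (0.5, -0.3, -0.6), (1.2, 0.8, 0.3), (-1.0, 2.0, 0.9)],
)
def test_rectangle_prob_matches_quadrature_oracle(z1, z2, rho):
    assert bvn_rectangle_prob(z1, z2, rho) == pytest.approx(
        dblquad_oracle(z1, z2, rho), abs=1e-8
    )


def test_rectangle_prob_independence_product():
    assert bvn_rectangle_prob(0.3, -0.7, 0.0) == pytest.approx(
        stats.norm.sf(0.3) * stats.norm.sf(-0.7), abs=1e-12
    )


# --- calibration ------------------------------------------------------------

def test_independence_gives_zero_rho():
    assert calibrate_latent_correlation(0.4, 0.5, 1.0) == pytest.approx(0.0, abs=1e-6)


def test_calibrated_rho_attains_target_or():
    for p1, p2, target in [(0.3, 0.3, 3.0), (0.485, 0.394, 0.724), (0.05, 0.08, 0.05)]:
        rho = calibrate_latent_correlation(p1, p2, target)
        z1, z2 = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
        p11 = dblquad_oracle(z1, z2, rho)  # independent oracle
        p10, p01 = p1 - p11, p2 - p11
        p00 = 1 - p1 - p2 + p11
        assert (p11 * p00) / (p10 * p01) == pytest.approx(target, rel=1e-4)


def test_rho_monotone_in_target_or():
    rhos = [
        calibrate_latent_correlation(0.3, 0.2, orr) for orr in (0.05, 0.5, 1.0, 2.0, 10.0)
    ]
    assert rhos == sorted(rhos)
    assert rhos[2] == pytest.approx(0.0, abs=1e-6)


def test_infeasible_or_reports_attainable_range():
    # a target beyond the numerically attainable latent-correlation range
    with pytest.raises(FeasibilityError, match="attainable"):
        calibrate_latent_correlation(0.9, 0.9, 1e12)


def test_invalid_inputs():
    with pytest.raises(ValueError):
        calibrate_latent_correlation(0.0, 0.5, 2.0)
    with pytest.raises(ValueError):
        calibrate_latent_correlation(0.3, 0.5, 0.0)


# --- profile simulation -----------------------------------------------------

def test_marginal_recovery_large_n():
    spec = CohortSpec(
        n_samples=100_000,
        marginals={"KRAS": 0.4, "TP53": 0.5, "BRAF": 0.1},
        seed=99,
    )
    m = simulate_profiles(spec)
    assert abs(m.df["KRAS"].mean() - 0.4) < 0.01
    assert abs(m.df["TP53"].mean() - 0.5) < 0.01
    assert abs(m.df["BRAF"].mean() - 0.1) < 0.01


def test_independent_genes_empirical_or_near_one():
    spec = CohortSpec(
        n_samples=100_000,
        marginals={"KRAS": 0.3, "TP53": 0.4},
        associations=[AssociationSpec("KRAS", "TP53", 1.0)],
        seed=5,
    )
    m = simulate_profiles(spec)
    or_, _ = odds_ratio(contingency_2x2(m, "KRAS", "TP53"))
    assert 0.93 < or_ < 1.07


def test_planted_exclusivity_detected_at_cohort_scale():
    from mapstrat import pairwise_scan

    hits = 0
    for s in range(10):
        spec = CohortSpec(
            n_samples=639,
            marginals={"KRAS": 0.39, "BRAF": 0.08},
            associations=[AssociationSpec("KRAS", "BRAF", 0.05)],
            seed=600 + s,
        )
        m = simulate_profiles(spec)
        res = pairwise_scan(m, min_mutations=5)
        pair = [r for r in res if {r.gene_a, r.gene_b} == {"KRAS", "BRAF"}]
        if pair and pair[0].direction.value == "exclusivity":
            hits += 1
    assert hits >= 6  # majority of replicates


def test_full_determinism_under_seed(paper_spec):
    m1 = simulate_profiles(paper_spec)
    m2 = simulate_profiles(paper_spec)
    assert m1.df.equals(m2.df)
    r1 = simulate_variant_records(m1, paper_spec)
    r2 = simulate_variant_records(m2, paper_spec)
    assert r1.records == r2.records
    assert r1.expected_excluded == r2.expected_excluded
    other = dataclasses.replace(paper_spec, seed=paper_spec.seed + 1)
    assert not simulate_profiles(other).df.equals(m1.df)


def test_psd_repair_reported(paper_spec):
    R, dist = build_latent_correlation(paper_spec)
    w = np.linalg.eigvalsh(R)
    assert w.min() > -1e-12
    assert np.allclose(np.diag(R), 1.0)
    assert dist >= 0.0


# --- variant-record layer ---------------------------------------------------

def test_noise_free_round_trip_is_lossless(paper_spec):
    spec = dataclasses.replace(
        paper_spec, n_samples=120, vus_rate=0.0, subthreshold_rate=0.0
    )
    m = simulate_profiles(spec)
    sim = simulate_variant_records(m, spec)
    assert sim.expected_excluded == set()
    cur = curate_cohort(sim.records, load_rules())
    m2 = build_matrix(cur, m.samples)
    assert m2.df.equals(m.df)


def test_vus_injection_excludes_exactly_expected(paper_spec):
    spec = dataclasses.replace(paper_spec, n_samples=150, vus_rate=0.1)
    m = simulate_profiles(spec)
    sim = simulate_variant_records(m, spec)
    assert sim.expected_excluded  # at ~34% sample-level rate this is non-empty
    cur = curate_cohort(sim.records, load_rules())
    assert cur.excluded_samples == sim.expected_excluded
    keep = [s for s in m.samples if s not in cur.excluded_samples]
    m2 = build_matrix(cur, keep)
    assert m2.df.equals(m.df.loc[keep])


def test_single_kras_vus_record_excluded_by_curation():
    from mapstrat import VariantRecord

    records = [
        VariantRecord("S1", "KRAS", "p.G12D", 12, 2, 500),
        VariantRecord("S2", "KRAS", "p.L19F", 19, 2, 500, "unannotated"),
    ]
    cur = curate_cohort(records, load_rules())
    assert cur.excluded_samples == {"S2"}


def test_covariates_msi_enriched_in_map41(paper_spec):
    spec = dataclasses.replace(paper_spec, n_samples=3000)
    m = simulate_profiles(spec)
    cov = simulate_covariates(m, spec)
    from mapstrat import assign_cohort

    a = assign_cohort(m)
    msi = cov["msi"] == "MSI-H"
    in41 = a.labels == "MAP4.1"
    assert msi[in41].mean() > msi[~in41].mean()
    assert set(cov.columns) == {"gender", "site", "side", "msi"}


# --- recovery report --------------------------------------------------------

def test_recovery_report_rank_order_and_cis():
    marg = {"KRAS": 0.3, "TP53": 0.4, "BRAF": 0.1, "NRAS": 0.15}
    assocs = [
        AssociationSpec("KRAS", "BRAF", 0.05),
        AssociationSpec("KRAS", "TP53", 1.0),
        AssociationSpec("TP53", "NRAS", 3.0),
    ]
    spec = CohortSpec(n_samples=200_000, marginals=marg, associations=assocs, seed=21)
    m = simulate_profiles(spec)
    rep = recovery_report(spec, m)
    marg_rows = rep[rep["kind"] == "marginal"]
    assert (abs(marg_rows["empirical"] - marg_rows["target"]) < 0.005).all()
    ors = rep[rep["kind"] == "odds_ratio"].set_index("name")["empirical"]
    assert ors["KRAS-BRAF"] < ors["KRAS-TP53"] < ors["TP53-NRAS"]


def test_recovery_report_small_n_no_spurious_failures():
    spec = CohortSpec(n_samples=10, marginals={"KRAS": 0.4, "TP53": 0.5}, seed=2)
    m = simulate_profiles(spec)
    rep = recovery_report(spec, m)
    marg = rep[rep["kind"] == "marginal"]
    assert (marg["ci_high"] - marg["ci_low"] > 0.3).all()  # wide CIs at n=10
    assert not marg["outside_ci"].any()
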