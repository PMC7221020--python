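"""Synthetic panel-sequencing cohorts with controlled association structure.

Correlated binary mutation profiles are generated through a latent Gaussian
copula: each gene g has a threshold z_g = Phi^-1(1 - p_g); a sample's latent
multivariate-normal vector is thresholded so gene g is mutated with marginal
probability p_g, and the latent correlation of each specified gene pair is
calibrated (by bisection on an exact bivariate-normal rectangle probability)
so that the pair's 2x2 cell probabilities attain a target odds ratio.
Mutual exclusivity is encoded as a small positive odds ratio (e.g. 0.05),
keeping the copula feasible.  On top of the binary profiles the generator
emits hotspot-style variant records with configurable VUS and sub-threshold
quality noise, and MAP-dependent clinical covariates, so the curation,
matrix, association, PCA, MAP and covariate stages are all exercisable
without any external data.

Higher-order (beyond pairwise) dependence is whatever the Gaussian copula
implies; it is not separately controlled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .curation import VariantRecord
from .errors import FeasibilityError
from .matrix import MutationMatrix
from .panel import PANEL, PANEL_INDEX

logger = logging.getLogger(__name__)

_N639 = 639  # reference cohort size the default spec emulates


def bvn_rectangle_prob(z1: float, z2: float, rho: float) -> float:
    """P(X > z1, Y > z2) for standard bivariate normal with correlation rho.

    Uses the identity Phi2(h, k; rho) = Phi(h)Phi(k) +
    (1/2pi) * int_0^rho exp(-(h^2 - 2 t h k + k^2) / (2(1-t^2))) / sqrt(1-t^2) dt
    evaluated at (h, k) = (-z1, -z2) with adaptive quadrature; deterministic
    and accurate to ~1e-10.
    """
    h, k = -z1, -z2
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base

    def integrand(t: float) -> float:
        om = 1.0 - t * t
        return math.exp(-(h * h - 2.0 * t * h * k + k * k) / (2.0 * om)) / math.sqrt(om)

    val, _ = integrate.quad(integrand, 0.0, rho, epsabs=1e-12, epsrel=1e-11, limit=200)
    return float(np.clip(base + val / (2.0 * math.pi), 0.0, 1.0))


def _cells_from_p11(p1: float, p2: float, p11: float) -> tuple[float, float, float, float]:
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    return p00, p01, p10, p11


def _or_from_rho(p1: float, p2: float, rho: float) -> float:
    z1 = stats.norm.ppf(1.0 - p1)
    z2 = stats.norm.ppf(1.0 - p2)
    p11 = bvn_rectangle_prob(z1, z2, rho)
    p00, p01, p10, p11 = _cells_from_p11(p1, p2, p11)
    if p11 <= 0.0 or p00 <= 0.0:
        return 0.0
    if p10 <= 0.0 or p01 <= 0.0:
        return math.inf
    return (p11 * p00) / (p10 * p01)


@lru_cache(maxsize=4096)
def calibrate_latent_correlation(
    p1: float, p2: float, target_or: float, tol: float = 1e-6
) -> float:
    """Latent correlation rho whose thresholded 2x2 attains ``target_or``.

    Solved by bisection (the odds ratio is strictly increasing in rho at
    fixed marginals).  For interior marginals the Frechet bounds on the
    joint-cell probabilities are reached only as |rho| -> 1, where the
    rectangle probability degenerates numerically; rho is therefore
    restricted to |rho| <= 1 - 1e-6 and a ``FeasibilityError`` reporting
    the attainable odds-ratio range is raised for targets beyond it.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("marginals must lie strictly in (0, 1)")
    if not (target_or > 0.0 and math.isfinite(target_or)):
        raise ValueError("target odds ratio must be finite and positive")
    lo, hi = -1.0 + 1e-6, 1.0 - 1e-6
    or_lo, or_hi = _or_from_rho(p1, p2, lo), _or_from_rho(p1, p2, hi)
    if not (or_lo < target_or < or_hi):
        raise FeasibilityError(
            f"odds ratio {target_or} unattainable for marginals ({p1}, {p2}); "
            f"attainable open range ({or_lo:.4g}, {or_hi:.4g})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        or_mid = _or_from_rho(p1, p2, mid)
        if abs(or_mid - target_or) <= tol * max(1.0, target_or):
            return mid
        if or_mid < target_or:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class AssociationSpec:
    """Target odds ratio for one gene pair (<<1 encodes mutual exclusivity)."""

    gene_a: str
    gene_b: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("association pair must be distinct")
        if not (self.odds_ratio > 0 and math.isfinite(self.odds_ratio)):
            raise ValueError("odds ratio must be finite and positive")


@dataclass(frozen=True)
class HotspotVariant:
    protein_change: str
    codon: int | None = None
    exon: int | None = None
    label: str = "pathogenic"


@dataclass
class CohortSpec:
    """Full parameterization of a synthetic cohort.

    ``marginals`` are per-gene mutation probabilities; ``associations`` the
    target pairwise odds ratios (unspecified pairs are independent);
    ``vus_rate`` the per-core-gene per-sample probability of an extra VUS
    record (which disqualifies the sample downstream); ``subthreshold_rate``
    the per-sample probability of an extra low-quality record.
    """

    n_samples: int
    marginals: Mapping[str, float]
    associations: Sequence[AssociationSpec] = ()
    vus_rate: float = 0.0
    subthreshold_rate: float = 0.0
    hotspots: Mapping[str, Sequence[HotspotVariant]] = field(default_factory=dict)
    vus_variants: Mapping[str, HotspotVariant] = field(default_factory=dict)
    msi_by_map: Mapping[str, float] = field(default_factory=dict)
    covariate_by_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, p in self.marginals.items():
            if g not in PANEL_INDEX:
                raise ValueError(f"marginal for non-panel gene {g!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal probability out of [0,1] for {g}: {p}")
        if not 0.0 <= self.vus_rate <= 1.0:
            raise ValueError("vus_rate must be in [0,1]")
        if not 0.0 <= self.subthreshold_rate <= 1.0:
            raise ValueError("subthreshold_rate must be in [0,1]")

    @property
    def genes(self) -> list[str]:
        return [g for g in PANEL if g in self.marginals]

    # ------------------------------------------------------------------
    @classmethod
    def paper_default(cls, n_samples: int = _N639, seed: int = 0, **kw) -> "CohortSpec":
        """The shipped default emulating a 639-sample metastatic CRC cohort.

        Marginals follow the published per-gene mutated-sample counts over
        639 (the tail genes below 1.5% get the small counts consistent with
        that bound); odds-ratio targets are the values implied by the
        published joint counts, with the three mutually exclusive RAS/RAF
        pairs encoded at OR = 0.05.
        """
        counts = {
            "KRAS": 252, "TP53": 310, "PIK3CA": 99, "BRAF": 51, "NRAS": 31,
            "FBXW7": 43, "SMAD4": 29, "PTEN": 21, "MET": 6, "STK11": 8,
            "EGFR": 11, "CTNNB1": 4, "AKT1": 5, "ERBB2": 3, "ERBB4": 2,
            "FGFR1": 2, "ALK": 1, "MAP2K1": 1, "NOTCH1": 2, "DDR2": 1,
            "FGFR3": 1, "FGFR2": 1,
        }
        marginals = {g: c / _N639 for g, c in counts.items()}
        associations = [
            AssociationSpec("KRAS", "TP53", 0.724),
            AssociationSpec("KRAS", "PIK3CA", 2.933),
            AssociationSpec("KRAS", "BRAF", 0.05),
            AssociationSpec("KRAS", "NRAS", 0.05),
            AssociationSpec("KRAS", "FBXW7", 1.843),
            AssociationSpec("KRAS", "EGFR", 4.197),
            AssociationSpec("BRAF", "NRAS", 0.05),
            AssociationSpec("PIK3CA", "FBXW7", 2.265),
            AssociationSpec("BRAF", "SMAD4", 3.275),
            AssociationSpec("BRAF", "PTEN", 3.442),
            AssociationSpec("EGFR", "SMAD4", 9.940),
            AssociationSpec("TP53", "NRAS", 2.716),
        ]
        # P(category | MAP) transcribed from the published covariate table.
        msi_by_map = {
            "MAP1.1": 0.0, "MAP1.2": 0.0, "MAP2.1": 0.0, "MAP2.2": 0.0,
            "MAP3.1": 2 / 27, "MAP3.2": 0.0, "MAP4.1": 6 / 9, "MAP4.2": 1 / 18,
        }
        covariate_by_map = {
            "male": {
                "MAP1.1": 29 / 44, "MAP1.2": 44 / 81, "MAP2.1": 35 / 63,
                "MAP2.2": 37 / 63, "MAP3.1": 44 / 85, "MAP3.2": 64 / 97,
                "MAP4.1": 34 / 56, "MAP4.2": 59 / 87,
            },
            "right_side": {
                "MAP1.1": 12 / 24, "MAP1.2": 31 / 48, "MAP2.1": 23 / 38,
                "MAP2.2": 18 / 37, "MAP3.1": 36 / 60, "MAP3.2": 15 / 51,
                "MAP4.1": 34 / 37, "MAP4.2": 14 / 36,
            },
            "colon_site": {
                "MAP1.1": 35 / 44, "MAP1.2": 67 / 81, "MAP2.1": 46 / 63,
                "MAP2.2": 58 / 63, "MAP3.1": 76 / 85, "MAP3.2": 84 / 97,
                "MAP4.1": 50 / 56, "MAP4.2": 70 / 86,
            },
        }
        spec = cls(
            n_samples=n_samples,
            marginals=marginals,
            associations=associations,
            vus_rate=0.048,  # ~18% of samples VUS-excluded across 4 core genes
            subthreshold_rate=0.05,
            hotspots=DEFAULT_HOTSPOTS,
            vus_variants=DEFAULT_VUS_VARIANTS,
            msi_by_map=msi_by_map,
            covariate_by_map=covariate_by_map,
            seed=seed,
        )
        return replace(spec, **kw) if kw else spec


DEFAULT_HOTSPOTS: dict[str, tuple[HotspotVariant, ...]] = {
    "KRAS": (
        HotspotVariant("p.G12D", 12, 2), HotspotVariant("p.G12V", 12, 2),
        HotspotVariant("p.G13D", 13, 2), HotspotVariant("p.A59T", 59, 3),
        HotspotVariant("p.Q61H", 61, 3), HotspotVariant("p.K117N", 117, 4),
        HotspotVariant("p.A146T", 146, 4),
    ),
    "TP53": (
        HotspotVariant("p.R175H", 175, 5), HotspotVariant("p.R248Q", 248, 7),
        HotspotVariant("p.R273H", 273, 8), HotspotVariant("p.R282W", 282, 8),
    ),
    "PIK3CA": (
        HotspotVariant("p.E542K", 542, 10), HotspotVariant("p.E545K", 545, 10),
        HotspotVariant("p.H1047R", 1047, 21),
    ),
    "BRAF": (HotspotVariant("p.V600E", 600, 15),),
    "NRAS": (HotspotVariant("p.Q61K", 61, 3), HotspotVariant("p.G12D", 12, 2)),
    "FBXW7": (HotspotVariant("p.R465C", 465, 9), HotspotVariant("p.R505C", 505, 10)),
    "SMAD4": (HotspotVariant("p.R361H", 361, 9),),
    "PTEN": (HotspotVariant("p.R130Q", 130, 5, "predicted_deleterious"),),
    "MET": (HotspotVariant("p.T1010I", 1010, 14, "predicted_deleterious"),),
    "STK11": (HotspotVariant("p.F354L", 354, 8, "predicted_deleterious"),),
    "EGFR": (HotspotVariant("p.L858R", 858, 21), HotspotVariant("p.G719S", 719, 18)),
    "CTNNB1": (HotspotVariant("p.S45F", 45, 3),),
    "AKT1": (HotspotVariant("p.E17K", 17, 3),),
    "ERBB2": (HotspotVariant("p.V842I", 842, 21),),
    "ERBB4": (HotspotVariant("p.E317K", 317, 8, "predicted_deleterious"),),
    "FGFR1": (HotspotVariant("p.N546K", 546, 12, "likely_pathogenic"),),
    "ALK": (HotspotVariant("p.F1174L", 1174, 23),),
    "MAP2K1": (HotspotVariant("p.K57N", 57, 2, "likely_pathogenic"),),
    "NOTCH1": (HotspotVariant("p.L1600Q", 1600, 26, "predicted_deleterious"),),
    "DDR2": (HotspotVariant("p.S768R", 768, 16, "predicted_deleterious"),),
    "FGFR3": (HotspotVariant("p.S249C", 249, 7),),
    "FGFR2": (HotspotVariant("p.S252W", 252, 7),),
}

#: One non-whitelist variant per core gene used to inject VUS records.
DEFAULT_VUS_VARIANTS: dict[str, HotspotVariant] = {
    "KRAS": HotspotVariant("p.L19F", 19, 2, "unannotated"),
    "BRAF": HotspotVariant("p.D594G", 594, 15, "unannotated"),
    "PIK3CA": HotspotVariant("p.R88Q", 88, 2, "unannotated"),
    "TP53": HotspotVariant("p.S99F", 99, 4, "unannotated"),
}


# ---------------------------------------------------------------------------
# latent correlation matrix

def build_latent_correlation(spec: CohortSpec) -> tuple[np.ndarray, float]:
    """Calibrated latent correlation matrix and its PSD-repair distance.

    Off-specified pairs are independent (rho = 0).  If the assembled matrix
    is not positive semidefinite it is repaired by clipping eigenvalues at
    1e-8 and rescaling back to unit diagonal; the Frobenius distance of the
    repair is returned (0.0 when no repair was needed) and logged.
    """
    genes = spec.genes
    idx = {g: i for i, g in enumerate(genes)}
    R = np.eye(len(genes))
    for assoc in spec.associations:
        p1, p2 = spec.marginals[assoc.gene_a], spec.marginals[assoc.gene_b]
        rho = calibrate_latent_correlation(p1, p2, assoc.odds_ratio)
        i, j = idx[assoc.gene_a], idx[assoc.gene_b]
        R[i, j] = R[j, i] = rho
    w, V = np.linalg.eigh(R)
    if w.min() >= 1e-8:
        return R, 0.0
    w_clip = np.clip(w, 1e-8, None)
    R2 = V @ np.diag(w_clip) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    dist = float(np.linalg.norm(R2 - R, "fro"))
    logger.info("latent correlation repaired to PSD; Frobenius distance %.3g", dist)
    return R2, dist


def simulate_profiles(spec: CohortSpec) -> MutationMatrix:
    """Sample the binary mutation matrix implied by the spec (seeded)."""
    genes = spec.genes
    R, _ = build_latent_correlation(spec)
    # tiny jitter guards the Cholesky after an exact-boundary repair
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(genes)))
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n_samples, len(genes))) @ L.T
    thresholds = stats.norm.ppf(
        [1.0 - spec.marginals[g] for g in genes]
    )
    mut = (Z > thresholds).astype(np.int8)
    samples = [f"S{i:05d}" for i in range(spec.n_samples)]
    df = pd.DataFrame(mut, index=samples, columns=genes)
    for g in PANEL:
        if g not in df.columns:
            df[g] = 0
    return MutationMatrix(df[list(PANEL)])


@dataclass
class SimulatedRecords:
    """Variant records plus the bookkeeping of expected VUS exclusions."""

    records: list[VariantRecord]
    expected_excluded: set[str]


def simulate_variant_records(m: MutationMatrix, spec: CohortSpec) -> SimulatedRecords:
    """Hotspot-style variant records realizing the binary matrix.

    Every 1-entry yields one retain-class record from the gene's hotspot
    vocabulary; core-gene VUS records are injected at ``vus_rate`` per
    sample and gene (flagging those samples as expected exclusions) and
    sub-threshold-quality records at ``subthreshold_rate`` per sample.
    Curating the records and rebuilding the matrix recovers ``m`` restricted
    to the non-excluded samples exactly.
    """
    hotspots = spec.hotspots or DEFAULT_HOTSPOTS
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    records: list[VariantRecord] = []
    expected_excluded: set[str] = set()
    core = [g for g in ("KRAS", "BRAF", "PIK3CA", "TP53") if g in m.genes]
    vus_vocab = spec.vus_variants or DEFAULT_VUS_VARIANTS
    all_genes = [g for g in m.genes if g in hotspots]
    for sample in m.samples:
        row = m.df.loc[sample]
        for gene in m.genes:
            if row[gene] != 1:
                continue
            if gene not in hotspots:
                raise ValueError(f"no hotspot vocabulary for mutated gene {gene!r}")
            hv = hotspots[gene][rng.integers(len(hotspots[gene]))]
            records.append(
                VariantRecord(
                    sample_id=sample,
                    gene=gene,
                    protein_change=hv.protein_change,
                    codon=hv.codon,
                    exon=hv.exon,
                    quality=float(rng.uniform(60.0, 900.0)),
                    pathogenicity_label=hv.label,
                )
            )
        if spec.vus_rate > 0:
            for gene in core:
                if rng.random() < spec.vus_rate:
                    vv = vus_vocab[gene]
                    records.append(
                        VariantRecord(
                            sample_id=sample,
                            gene=gene,
                            protein_change=vv.protein_change,
                            codon=vv.codon,
                            exon=vv.exon,
                            quality=float(rng.uniform(60.0, 900.0)),
                            pathogenicity_label=vv.label,
                        )
                    )
                    expected_excluded.add(sample)
        if spec.subthreshold_rate > 0 and rng.random() < spec.subthreshold_rate:
            gene = all_genes[rng.integers(len(all_genes))]
            hv = hotspots[gene][rng.integers(len(hotspots[gene]))]
            records.append(
                VariantRecord(
                    sample_id=sample,
                    gene=gene,
                    protein_change=hv.protein_change,
                    codon=hv.codon,
                    exon=hv.exon,
                    quality=float(rng.uniform(1.0, 29.0)),
                    pathogenicity_label=hv.label,
                )
            )
    return SimulatedRecords(records, expected_excluded)


def simulate_covariates(m: MutationMatrix, spec: CohortSpec) -> pd.DataFrame:
    """MAP-dependent clinical covariates (gender, site, side, MSI)."""
    from .mapping import assign_cohort

    a = assign_cohort(m)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    rows = []
    for sample, lab in a.labels.items():
        p_male = spec.covariate_by_map.get("male", {}).get(lab, 0.5)
        p_right = spec.covariate_by_map.get("right_side", {}).get(lab, 0.5)
        p_colon = spec.covariate_by_map.get("colon_site", {}).get(lab, 0.85)
        p_msi = spec.msi_by_map.get(lab, 0.0)
        rows.append(
            {
                "sample_id": sample,
                "gender": "M" if rng.random() < p_male else "F",
                "site": "Colon" if rng.random() < p_colon else "Rectum",
                "side": "Right" if rng.random() < p_right else "Left",
                "msi": "MSI-H" if rng.random() < p_msi else "MSS",
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def recovery_report(spec: CohortSpec, m: MutationMatrix) -> pd.DataFrame:
    """Target-vs-empirical marginals and odds ratios with 95% CIs.

    Marginal CIs are Wilson binomial intervals; odds-ratio CIs use the
    log-OR normal approximation on the (Haldane-corrected if needed) table.
    ``outside_ci`` flags targets outside their empirical interval.
    """
    from statsmodels.stats.proportion import proportion_confint

    from .association import contingency_2x2, odds_ratio

    n = m.n_samples
    rows = []
    for g in spec.genes:
        c = int(m.df[g].sum())
        lo, hi = proportion_confint(c, n, alpha=0.05, method="wilson")
        target = spec.marginals[g]
        rows.append(
            {
                "kind": "marginal",
                "name": g,
                "target": target,
                "empirical": c / n,
                "ci_low": lo,
                "ci_high": hi,
                "outside_ci": not (lo <= target <= hi),
            }
        )
    for assoc in spec.associations:
        t = contingency_2x2(m, assoc.gene_a, assoc.gene_b)
        or_, corrected = odds_ratio(t)
        a, b, c, d = t.a, t.b, t.c, t.d
        if corrected:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(or_) - 1.96 * se)
        hi = math.exp(math.log(or_) + 1.96 * se)
        rows.append(
            {
                "kind": "odds_ratio",
                "name": f"{assoc.gene_a}-{assoc.gene_b}",
                "target": assoc.odds_ratio,
                "empirical": or_,
                "ci_low": lo,
                "ci_high": hi,
                "outside_ci": not (lo <= assoc.odds_ratio <= hi),
            }
        )
    return pd.DataFrame(rows)
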