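# Methods

## The analysis model

The object of study is a cohort of tumor samples typed on a 22-gene hotspot
panel, reduced to a binary matrix `M` with `M[i,j] = 1` when sample `i`
carries at least one curated, clinically relevant mutation in gene `j`.
Everything downstream treats this matrix as the data: the panel's hotspot
design means absence of a call is "no hotspot mutation detected", not "gene
wild-type genome-wide", and copy-number changes and rearrangements are
invisible. Mutation-free samples are cohort members (they form their own
stratification group), so all-zero rows are never dropped.

### Curation

Calls are filtered in a fixed order: caller quality first (threshold 30 on
the caller's own scale — unreliable calls should never reach biological
rules), then benign labels, then the gene rule. Gene rules are data
(`mapstrat/data/default_rules.yaml`), not code:

* KRAS — activating codons 12, 13, 59, 61, 117, 146;
* BRAF — V600E only;
* PIK3CA — hotspot exons, default {10, 21} in the numbering of the panel's
  reference transcript (other transcript schemes number the same regions
  9/20; the default follows the panel's convention and is configurable);
* TP53 — pathogenic / likely-pathogenic label, or membership in a
  configurable hotspot-codon list (an offline stand-in for a live ClinVar
  query, which this package deliberately never makes);
* all other genes — pathogenic / likely-pathogenic / predicted-deleterious
  label.

A record failing its gene rule with a non-benign label is a VUS. A VUS in
one of the four core genes (KRAS, BRAF, PIK3CA, TP53) excludes the whole
sample — a VUS there undermines the interpretability of the sample's
profile, whereas a VUS in a minor gene is merely dropped. Protein changes
are parsed in `p.`-prefixed or bare, one- or three-letter forms, and the
codon is recovered from the string when the codon field is absent.

### Pairwise association

Genes with more than 10 mutated samples (≈ 1.5% of a 639-sample cohort)
enter the scan; rarer genes yield tables too sparse to interpret. Each
unordered pair gets a 2×2 joint-status table tested with Pearson's χ²
(df = 1, **no Yates continuity correction**) or two-sided Fisher exact
(minimum-likelihood convention, the dominant software convention) — Fisher
whenever any expected cell count is below 5 or a margin is zero. The
no-correction and expected-count-rule choices were validated against the
reference study's printed p-values and test-selection footnotes, which they
reproduce exactly; Yates-corrected values do not. Significance is raw
p < 0.05 with no multiplicity correction, matching the descriptive practice
of panel-report studies (a Benjamini–Hochberg option exists, default off).
Odds ratios use the Haldane–Anscombe +0.5 correction on zero-cell tables,
flagged in the result.

### PCA stratification

Covariance PCA on the column-centered (not variance-scaled) 0/1 matrix:
the columns share a scale already, and dividing by the standard deviation
would inflate rarely mutated genes into spurious stratifiers. Loading signs
follow a deterministic convention (largest-magnitude entry of each
component positive) so outputs are bit-stable. Candidate stratifiers are
ranked by maximum absolute loading over the first two components, ties
broken by panel order. "Sharpness" of a candidate pair is the mean
silhouette coefficient, in PC1–PC2 score space with Euclidean distance, of
the ≤ 4 groups induced by the pair's joint status; any monotone alternative
could be swapped behind the same contract.

### MAP assignment

With stratifiers (TP53, KRAS) — a parameter, defaulting to the pair the
PCA stage selects on mCRC-like cohorts, so the PCA output can drive
assignment end to end — the main group is mut/mut → MAP1, wt/mut → MAP2,
mut/wt → MAP3, wt/wt → MAP4, and the sub-label is ".1" iff ≥ 1 mutation
among the other 20 genes. The assignment is a total, deterministic
partition; MAP4.2 ⇔ all-zero row. Per-MAP gene frequencies in empty MAPs
are reported as undefined (NaN), never 0, to avoid fabricating zeros in
small cohorts. Therapy annotations per MAP are a static YAML lookup —
descriptive configuration, not an evidence engine.

### Covariate association

Category × MAP tables keep all 8 MAP columns (zeros for empty MAPs) and
drop samples with missing covariate listwise per covariate. Tests: Pearson
χ² with df = (r−1)(c−1) after dropping all-zero rows/columns, or — when any
expected count is < 5 — a seeded Monte-Carlo version of Fisher's exact
test: B (default 100 000) tables are sampled at fixed margins by permuting
the expanded column-label vector, and p = (1 + #{P(T) ≤ P(obs)}) / (B + 1),
reported with its binomial standard error. An exact network algorithm was
deliberately not implemented: at B = 10⁵ the Monte-Carlo standard error
(< 0.0016) is far below any decision threshold used here, and the estimate
is bit-reproducible under the seed. Cross-cohort MAP-rate comparison is
descriptive (percentages and differences in points) with an exploratory
pooled two-proportion z-test.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes,
via a latent Gaussian copula: gene `g` gets threshold
`z_g = Φ⁻¹(1 − p_g)`; a correlated standard-normal vector is thresholded so
marginal mutation probabilities are exact by construction, and each
specified pair's latent correlation is calibrated by bisection so the
implied 2×2 cell probabilities hit a target odds ratio within 1e-6
(relative). The bivariate-normal rectangle probability is computed by the
one-dimensional Plackett integral with adaptive quadrature (deterministic,
~1e-10 accurate); tests cross-check it against an independent double
quadrature. Mutual exclusivity is encoded as OR = 0.05 rather than a
structural zero, keeping the copula feasible. The copula was chosen over
sequential-logistic or Bahadur-expansion constructions because it
guarantees the marginals for arbitrary pairwise targets; higher-order
dependence is implied, not controlled — a documented limitation.

The pairwise targets of the default spec are jointly infeasible as a
correlation matrix (three mutually exclusive RAS/RAF pairs plus a KRAS hub
force indefiniteness), so the assembled matrix is repaired to the nearest
positive-semidefinite correlation by eigenvalue clipping at 1e-8 and
rescaling to unit diagonal. The repair's Frobenius distance is logged
(≈ 0.29 for the default spec); it compresses extreme odds ratios toward 1
(e.g. a 0.05 exclusivity target realizes near 0.12) while preserving every
association's direction and all marginals — the properties the downstream
acceptance checks rely on. Over-constrained user specs can detect
themselves the same way.

Default parameters (`CohortSpec.paper_default`): n = 639; marginals equal
to the reference study's per-gene mutated-sample counts over 639 (KRAS
252, TP53 310, PIK3CA 99, BRAF 51, FBXW7 43, NRAS 31, SMAD4 29, PTEN 21,
EGFR 11, and small counts for the <1.5% tail genes); odds-ratio targets
computed from the study's reconstructed joint tables; per-core-gene VUS
rate 0.048 per sample (so ≈ 18% of samples are VUS-excluded across the four
core genes, matching the study's exclusion fraction); sub-threshold-quality
record rate 0.05; covariate model P(category | MAP) transcribed from the
study's covariate table (MSI-high concentrated in MAP4.1). On top of the
matrix, every 1-entry emits one retain-class hotspot record (quality
uniform on [60, 900]); VUS records use per-gene variant strings disjoint
from the hotspot vocabulary so label-conflict checking stays clean.
Round-tripping records through curation and matrix building recovers the
matrix restricted to non-excluded samples exactly, and the expected
exclusion set is returned for bookkeeping.

What the generator does **not** emulate: allele frequencies / VAF, clonal
architecture, read-level errors, within-MAP joint distributions beyond the
pairwise summaries, and inter-gene dependence beyond second order. Passing
tests therefore demonstrate that the pipeline recovers planted marginal and
pairwise structure and honors its own contracts — not that real FFPE panel
data meets the copula's assumptions.

## Problem sizes and numerical choices

The test and acceptance workloads use n = 639 for replicate-level checks
(100 replicates for stratifier recovery, 200 for association directions —
the cohort scale the defaults emulate), n = 200 000 for one-shot parameter
recovery (binomial noise ≈ 0.1 percentage points, comfortably inside the
±0.5-point tolerance), and B = 20 000–30 000 Monte-Carlo tables when
comparing against exhaustive r×c enumeration on tiny tables. Direction
recovery is judged on the odds-ratio sign of each scanned pair (co-occur
> 1, exclude < 1) rather than on significance, which at n = 639 is
underpowered for the weakest reference associations. The replicate scans
use an eligibility floor of 5 mutated samples so that genes whose expected
count sits exactly at the 11-sample threshold (EGFR at ≈ 11/639) remain in
every replicate's scan.

Percentages are rounded half-up to one decimal (clinical-table convention;
banker's rounding would print 18.15 → 18.1). Latent correlations are
restricted to |ρ| ≤ 1 − 1e-6; targets outside the attainable odds-ratio
range raise a feasibility error reporting that range. Bisection runs to an
OR tolerance of 1e-6 (relative) or an interval of 1e-14.

## Known limitations

* Curation rules encode one clinical convention; they are configuration,
  and the shipped defaults are not a substitute for local molecular-board
  policy. The TP53 hotspot-codon list is a frozen snapshot, not ClinVar.
* Raw p-values with no multiplicity correction mirror descriptive panel
  studies; for inferential use, enable the FDR option.
* The r×c exact test is Monte-Carlo; p-values near a decision boundary
  should be read with their reported standard error.
* PCA on binary data is a pragmatic variance decomposition, not a model of
  binary likelihoods (no logistic PCA / MCA).
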