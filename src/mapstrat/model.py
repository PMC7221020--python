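"""statsmodels-style facade: one model object over the mutation matrix.

``MutationPatternModel`` wraps a binary ``MutationMatrix`` (plus optional
clinical covariates); ``fit()`` runs the full analysis — PCA stratifier
selection, pairwise association scan, MAP assignment — and returns a
``MutationPatternResults`` carrying the estimates (odds ratios), their
p-values, diagnostics (explained variance, separation score) and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .association import MIN_MUTATIONS, PairwiseResult, pairwise_scan, results_frame
from .covariates import covariate_map_table, rxc_association_p
from .mapping import MapAssignment, assign_cohort, map_composition, per_map_gene_frequency
from .matrix import MutationMatrix, mutation_frequencies
from .pca import PcaResult, rank_stratifiers, run_pca, separation_score


@dataclass
class MutationPatternResults:
    model: "MutationPatternModel"
    pca: PcaResult
    stratifiers: tuple[str, str]
    separation: float
    pairwise: list[PairwiseResult]
    assignment: MapAssignment
    composition: pd.DataFrame
    per_map_frequency: pd.DataFrame
    covariate_tests: pd.DataFrame | None = None

    @property
    def pairwise_frame(self) -> pd.DataFrame:
        return results_frame(self.pairwise)

    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "Mutational Association Pattern analysis",
            "=" * 55,
            f"Samples: {m.n_samples}    Genes: {len(m.genes)}",
            f"Stratifier pair: {self.stratifiers[0]}/{self.stratifiers[1]} "
            f"(separation score {self.separation:.3f})",
            "PC1/PC2 explained variance: "
            + " ".join(f"{v:.1%}" for v in self.pca.explained_variance_ratio[:2]),
            "",
            "MAP composition:",
            self.composition.to_string(),
            "",
            "Significant pairwise associations (raw p < alpha):",
        ]
        sig = self.pairwise_frame.query("significant")
        if len(sig):
            lines.append(
                sig[["gene_a", "gene_b", "test", "p_value", "odds_ratio", "direction"]]
                .to_string(index=False)
            )
        else:
            lines.append("  (none)")
        if self.covariate_tests is not None and len(self.covariate_tests):
            lines += ["", "Covariate vs MAP associations:", self.covariate_tests.to_string()]
        return "\n".join(lines)


@dataclass
class MutationPatternModel:
    """The MAP analysis as a fittable model over a binary mutation matrix."""

    matrix: MutationMatrix
    covariates: pd.DataFrame | None = None
    min_mutations: int = MIN_MUTATIONS
    alpha: float = 0.05
    _fixed_stratifiers: tuple[str, str] | None = field(default=None, repr=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariates: pd.DataFrame | None = None, **kw
    ) -> "MutationPatternModel":
        return cls(MutationMatrix(df), covariates=covariates, **kw)

    def fit(
        self,
        stratifiers: tuple[str, str] | None = None,
        n_components: int = 2,
        seed: int = 0,
    ) -> MutationPatternResults:
        """Run PCA, pairwise scan, MAP assignment and covariate tests.

        With ``stratifiers=None`` the pair is the top-2 genes by absolute
        PCA loading over the first two components (data-driven, the default);
        passing a pair pins it.
        """
        pca = run_pca(self.matrix, n_components=n_components)
        if stratifiers is None:
            stratifiers = self._fixed_stratifiers
        if stratifiers is None:
            top = rank_stratifiers(pca, k=min(2, n_components))
            stratifiers = (top[0], top[1])
        sep = separation_score(self.matrix, stratifiers, pca)
        pw = pairwise_scan(self.matrix, alpha=self.alpha, min_mutations=self.min_mutations)
        assignment = assign_cohort(self.matrix, stratifiers=stratifiers)
        comp = map_composition(assignment)
        freq = per_map_gene_frequency(self.matrix, assignment)
        cov_tests = None
        if self.covariates is not None:
            rows = []
            for name in self.covariates.columns:
                try:
                    tab = covariate_map_table(assignment, self.covariates[name], name)
                    p, se = rxc_association_p(tab, method="auto", seed=seed)
                except Exception as exc:  # degenerate covariate: report, don't fail
                    rows.append({"covariate": name, "p_value": float("nan"),
                                 "mc_se": None, "note": str(exc)})
                    continue
                rows.append({"covariate": name, "p_value": p, "mc_se": se, "note": ""})
            cov_tests = pd.DataFrame(rows).set_index("covariate")
        return MutationPatternResults(
            model=self,
            pca=pca,
            stratifiers=stratifiers,
            separation=sep,
            pairwise=pw,
            assignment=assignment,
            composition=comp,
            per_map_frequency=freq,
            covariate_tests=cov_tests,
        )

    @property
    def gene_frequencies(self) -> pd.DataFrame:
        return mutation_frequencies(self.matrix)
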