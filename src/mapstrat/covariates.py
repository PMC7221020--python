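"""Clinical-covariate association with MAPs, and cross-cohort comparison.

Category x MAP contingency tables are tested with Pearson's chi-square or,
when expected counts are small, a seeded Monte-Carlo version of Fisher's
exact test for r x c tables (tables sampled at fixed margins; the two-sided
p is the probability of a table at most as likely as the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DegenerateInputError

if TYPE_CHECKING:  # pragma: no cover
    from .mapping import MapAssignment


@dataclass
class CovariateTable:
    """Covariate categories (rows) x MAP labels (columns) counts."""

    counts: pd.DataFrame
    covariate: str
    n_missing: int = 0

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def covariate_map_table(
    a: "MapAssignment", covariate: Mapping[str, object] | pd.Series, name: str = "covariate"
) -> CovariateTable:
    """Cross-tabulate MAP labels against one clinical covariate.

    Samples with a missing covariate value are excluded listwise and
    counted in ``n_missing``.  Columns for empty MAPs are retained (zeros)
    so every table has the fixed r x 8 shape.
    """
    from .mapping import MAP_LABELS

    cov = pd.Series(covariate)
    cov = cov.reindex(a.labels.index)
    present = cov.notna()
    n_missing = int((~present).sum())
    cov = cov[present]
    if cov.nunique() < 2:
        raise DegenerateInputError(
            f"covariate {name!r} has <2 categories after dropping missing values"
        )
    tab = pd.crosstab(cov, a.labels[present])
    tab = tab.reindex(columns=list(MAP_LABELS), fill_value=0)
    return CovariateTable(counts=tab, covariate=name, n_missing=n_missing)


def _log_table_prob(table: np.ndarray, logfact_margins: float, logn: float) -> float:
    # log multivariate hypergeometric probability at fixed margins
    return logfact_margins - logn - gammaln(table + 1.0).sum()


def _mc_fisher(table: np.ndarray, b: int, rng: np.random.Generator) -> tuple[float, float]:
    """Monte-Carlo two-sided Fisher for an r x c table at fixed margins.

    Tables are sampled by permuting the column labels of the expanded
    observation vector; p = (1 + #{P(T) <= P(obs)}) / (b + 1), reported with
    its binomial Monte-Carlo standard error.
    """
    r_marg = table.sum(axis=1)
    c_marg = table.sum(axis=0)
    n = int(table.sum())
    logfact_margins = gammaln(r_marg + 1.0).sum() + gammaln(c_marg + 1.0).sum()
    logn = gammaln(n + 1.0)
    obs_logp = _log_table_prob(table, logfact_margins, logn)

    rows = np.repeat(np.arange(len(r_marg)), r_marg)
    cols = np.repeat(np.arange(len(c_marg)), c_marg)
    nr, nc = len(r_marg), len(c_marg)
    hits = 0
    for _ in range(b):
        perm = rng.permutation(cols)
        t = np.bincount(rows * nc + perm, minlength=nr * nc).reshape(nr, nc)
        if _log_table_prob(t, logfact_margins, logn) <= obs_logp + 1e-9:
            hits += 1
    p = (1 + hits) / (b + 1)
    se = float(np.sqrt(p * (1 - p) / b))
    return p, se


def rxc_association_p(
    t: CovariateTable | pd.DataFrame | np.ndarray,
    method: str = "auto",
    b: int = 100_000,
    seed: int | None = 0,
) -> tuple[float, float | None]:
    """(p_value, mc_standard_error) for an r x c association test.

    ``chi2``: Pearson chi-square with df = (r-1)(c-1) after dropping
    all-zero columns.  ``exact_mc``: seeded Monte-Carlo Fisher (``b``
    sampled tables).  ``auto`` uses exact_mc whenever any expected count is
    below 5.  The second element is the Monte-Carlo standard error (None
    for chi-square).
    """
    if isinstance(t, CovariateTable):
        arr = t.counts.to_numpy(dtype=np.int64)
    elif isinstance(t, pd.DataFrame):
        arr = t.to_numpy(dtype=np.int64)
    else:
        arr = np.asarray(t, dtype=np.int64)
    arr = arr[:, arr.sum(axis=0) > 0]
    arr = arr[arr.sum(axis=1) > 0, :]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateInputError(
            "association test needs >=2 non-empty rows and columns"
        )
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if method == "auto":
        method = "exact_mc" if expected.min() < 5 else "chi2"
    if method == "chi2":
        res = stats.chi2_contingency(arr, correction=False)
        return float(res.pvalue), None
    if method == "exact_mc":
        rng = np.random.default_rng(seed)
        return _mc_fisher(arr, b, rng)
    raise ValueError(f"unknown method {method!r}")


def compare_map_rates(
    a_counts: Mapping[str, int] | pd.Series, b_counts: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Per-MAP rate comparison between two cohorts.

    Descriptive percentages and differences (percentage points), with an
    exploratory two-proportion z-test per MAP.
    """
    from statsmodels.stats.proportion import proportions_ztest

    from .mapping import MAP_LABELS
    from .matrix import round_pct

    ca = pd.Series(a_counts).reindex(MAP_LABELS, fill_value=0).astype(int)
    cb = pd.Series(b_counts).reindex(MAP_LABELS, fill_value=0).astype(int)
    na, nb = int(ca.sum()), int(cb.sum())
    if na == 0 or nb == 0:
        raise DegenerateInputError("both cohorts must be non-empty")
    rows = []
    for lab in MAP_LABELS:
        pa = round_pct(100.0 * ca[lab] / na)
        pb = round_pct(100.0 * cb[lab] / nb)
        if ca[lab] + cb[lab] in (0, na + nb):
            z, p = 0.0, 1.0
        else:
            z, p = proportions_ztest([ca[lab], cb[lab]], [na, nb])
        rows.append(
            {
                "map": lab,
                "count_a": int(ca[lab]),
                "count_b": int(cb[lab]),
                "pct_a": pa,
                "pct_b": pb,
                "diff_points": round_pct(pa - pb),
                "z_p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("map")
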