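"""Case-control association of CNV copy-number genotypes.

The primary contrast dichotomizes diploid copy totals into low {2,3} vs
high {4,5,6} carriers and tests the 2x2 status-by-copy-group table with
Fisher's exact test, reporting the sample odds ratio (cross-product ad/bc),
the conditional-MLE odds ratio from the exact test's noncentral
hypergeometric likelihood, and a Woolf 95% confidence interval.  The full
five-category copy distribution (2-6) is tested with a margin-fixed exact
2xK test (complete enumeration for small tables, Monte-Carlo otherwise).
Age adjustment uses binary logistic regression, and the onset analyses
compare the lapse from first use to dependence between copy groups
(Mann-Whitney U) and its early/late (<1 y vs >=1 y) dichotomy (one-tailed
exact test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact as _scipy_fisher, mannwhitneyu, norm
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "SubjectRecord",
    "ContingencyTable",
    "AssociationResult",
    "ExactTestResult",
    "dichotomize",
    "copy_category_table",
    "fisher_exact_2x2",
    "fisher_exact_2xK",
    "logistic_adjust",
    "onset_analysis",
    "woolf_interval",
]

LOW_SET_DEFAULT = frozenset({2, 3})
COPY_CATEGORIES = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SubjectRecord:
    sample_id: str
    status: str  # "case" | "control"
    total_copies: int
    age: float
    sex: str
    onset_years: float | None = None  # lapse first use -> dependence; cases only

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case|control, got {self.status!r}")
        if not 2 <= self.total_copies <= 6:
            raise ValueError(f"total copies {self.total_copies} outside [2, 6]")
        if self.onset_years is not None and self.status != "case":
            raise ValueError("onset lapse is defined for cases only")


@dataclass
class ContingencyTable:
    """Counts with row labels (status) and column labels (copy categories)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.counts.sum(axis=1, keepdims=True)


@dataclass
class AssociationResult:
    table: ContingencyTable
    p_value: float
    or_sample: float
    or_cmle: float
    ci_low: float
    ci_high: float
    sidedness: str
    flags: list[str] = field(default_factory=list)


@dataclass
class ExactTestResult:
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    n_tables: int | None = None
    mc_standard_error: float | None = None


def woolf_interval(a: int, b: int, c: int, d: int, level: float = 0.95) -> tuple[float, float]:
    """Woolf (log-normal) CI for the sample odds ratio ad/bc."""
    if min(a, b, c, d) == 0:
        raise ValueError("Woolf interval undefined with a zero cell")
    z = norm.ppf(0.5 + level / 2.0)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def _subject_frame(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "status": s.status,
                "total_copies": s.total_copies,
                "age": s.age,
                "sex": s.sex,
                "onset_years": s.onset_years,
            }
            for s in subjects
        ]
    )
    if df.empty:
        raise ValueError("no subjects")
    return df


def dichotomize(
    subjects: Iterable[SubjectRecord],
    low_set: frozenset[int] | set[int] = LOW_SET_DEFAULT,
) -> ContingencyTable:
    """2x2 table of status (cases, controls) by copy group (low, high).

    ``low_set`` defaults to {2,3}; passing {2,3,4} reproduces the
    sensitivity re-partition.  Row order is (case, control) and column order
    (low, high), so the cross-product OR measures the enrichment of low
    copy numbers in cases.
    """
    df = _subject_frame(subjects)
    low = df["total_copies"].isin(low_set)
    counts = np.array(
        [
            [int(((df.status == "case") & low).sum()), int(((df.status == "case") & ~low).sum())],
            [int(((df.status == "control") & low).sum()), int(((df.status == "control") & ~low).sum())],
        ]
    )
    return ContingencyTable(counts, ("case", "control"), ("low", "high"))


def copy_category_table(subjects: Iterable[SubjectRecord]) -> ContingencyTable:
    """2x5 table of status by exact copy number (2..6)."""
    df = _subject_frame(subjects)
    counts = np.array(
        [
            [int(((df.status == st) & (df.total_copies == k)).sum()) for k in COPY_CATEGORIES]
            for st in ("case", "control")
        ]
    )
    return ContingencyTable(counts, ("case", "control"), tuple(str(k) for k in COPY_CATEGORIES))


def fisher_exact_2x2(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    sidedness: str = "two",
    alternative: str = "greater",
) -> AssociationResult:
    """Fisher's exact test on a 2x2 table with OR estimates and Woolf CI.

    The two-tailed p sums all margin-fixed tables whose hypergeometric
    probability does not exceed the observed one.  ``or_sample`` is ad/bc;
    ``or_cmle`` maximizes the conditional (noncentral hypergeometric)
    likelihood — the estimate printed by classical exact-test software.
    With a zero cell the sample OR degenerates to 0 or infinity and the CI
    is undefined (NaN, flagged).
    """
    if isinstance(table, ContingencyTable):
        ct = table
    else:
        ct = ContingencyTable(np.asarray(table), ("row1", "row2"), ("col1", "col2"))
    if ct.counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    a, b = ct.counts[0]
    c, d = ct.counts[1]
    if sidedness == "two":
        alt = "two-sided"
    elif sidedness == "one":
        alt = alternative
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    p = float(_scipy_fisher(ct.counts, alternative=alt).pvalue)
    flags: list[str] = []
    if min(a, b, c, d) == 0:
        or_sample = math.inf if (a * d > 0) else 0.0
        ci_low = ci_high = math.nan
        flags.append("zero_cell")
    else:
        or_sample = (a * d) / (b * c)
        ci_low, ci_high = woolf_interval(a, b, c, d)
    or_cmle = float(_scipy_odds_ratio(ct.counts, kind="conditional").statistic)
    return AssociationResult(
        table=ct,
        p_value=p,
        or_sample=or_sample,
        or_cmle=or_cmle,
        ci_low=ci_low,
        ci_high=ci_high,
        sidedness=sidedness,
        flags=flags,
    )


def _log_table_prob(top: Sequence[int], col_sums: Sequence[int], n: int, r1: int) -> float:
    """log P(top row | margins) under the margin-fixed null.

    P = prod_j C(c_j, a_j) / C(n, r1): draw which r1 of the n subjects fall
    in row 1, uniformly over subsets.
    """
    logp = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    for a_j, c_j in zip(top, col_sums):
        logp += gammaln(c_j + 1) - gammaln(a_j + 1) - gammaln(c_j - a_j + 1)
    return float(logp)


def _enumerate_top_rows(col_sums: Sequence[int], r1: int):
    """Yield every non-negative top row with a_j <= c_j summing to r1."""
    k = len(col_sums)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == k - 1:
            if remaining <= col_sums[j]:
                yield prefix + [remaining]
            return
        tail_capacity = sum(col_sums[j + 1:])
        lo = max(0, remaining - tail_capacity)
        hi = min(col_sums[j], remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + [a])

    yield from rec(0, r1, [])


def _count_tables(col_sums: Sequence[int], r1: int) -> int:
    """Number of margin-fixed tables (distinct valid top rows), by DP."""
    counts = {0: 1}
    for c_j in col_sums:
        new: dict[int, int] = {}
        for s, m in counts.items():
            for a in range(0, min(c_j, r1 - s) + 1):
                new[s + a] = new.get(s + a, 0) + m
        counts = new
    return counts.get(r1, 0)


def fisher_exact_2xK(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    enumeration_budget: int = 2_000_000,
    mc_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> ExactTestResult:
    """Exact test of independence for a 2xK table with fixed margins.

    The p-value sums the probabilities of all margin-fixed tables whose
    multivariate hypergeometric probability is at most the observed one
    (the standard "probability at most observed" two-sided rule; for K = 2
    this reduces to the two-tailed 2x2 Fisher test).  When the number of
    candidate tables exceeds ``enumeration_budget`` the p-value is
    estimated by Monte-Carlo sampling of the null (column totals drawn into
    row 1 by multivariate hypergeometric sampling), with its binomial
    standard error reported.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=int)
    if counts.ndim != 2 or counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("need a 2xK table with K >= 2")
    if (counts < 0).any():
        raise ValueError("negative counts")
    col_sums = counts.sum(axis=0)
    keep = col_sums > 0  # empty columns carry no information
    counts = counts[:, keep]
    col_sums = col_sums[keep]
    n = int(counts.sum())
    r1 = int(counts[0].sum())
    if n == 0 or r1 == 0 or r1 == n or counts.shape[1] < 2:
        return ExactTestResult(p_value=1.0, method="enumeration", n_tables=1)

    log_obs = _log_table_prob(counts[0], col_sums, n, r1)
    slack = 1e-9 * abs(log_obs)  # float-noise guard on the <= comparison

    n_tables = _count_tables(col_sums.tolist(), r1)
    if n_tables <= enumeration_budget:
        p = 0.0
        for top in _enumerate_top_rows(col_sums.tolist(), r1):
            lp = _log_table_prob(top, col_sums, n, r1)
            if lp <= log_obs + slack + 1e-12:
                p += math.exp(lp)
        return ExactTestResult(p_value=min(p, 1.0), method="enumeration", n_tables=n_tables)

    rng = rng or np.random.default_rng()
    draws = rng.multivariate_hypergeometric(col_sums, r1, size=mc_draws)
    logps = np.array([_log_table_prob(t, col_sums, n, r1) for t in draws])
    hits = int((logps <= log_obs + slack + 1e-12).sum())
    p_hat = hits / mc_draws
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / mc_draws) / mc_draws)
    return ExactTestResult(p_value=p_hat, method="monte_carlo", mc_standard_error=se)


def logistic_adjust(
    subjects: Iterable[SubjectRecord],
    low_set: frozenset[int] | set[int] = LOW_SET_DEFAULT,
    covariates: Sequence[str] = ("age",),
) -> dict:
    """Binary logistic regression of case status on the low-copy indicator.

    Returns the covariate-adjusted odds ratio for carrying a low copy total
    with its Wald p-value and 95% CI.  Degenerate designs fail loudly:
    zero-variance covariates raise ValueError and (quasi-)complete
    separation raises RuntimeError instead of returning a silently diverged
    fit.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    df = _subject_frame(subjects)
    y = (df["status"] == "case").astype(float)
    X = pd.DataFrame({"low_copy": df["total_copies"].isin(low_set).astype(float)})
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        col = pd.to_numeric(df[cov])
        if col.nunique() < 2:
            raise ValueError(f"covariate {cov!r} has zero variance")
        X[cov] = col
    X = sm.add_constant(X, has_constant="add")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is re-raised below
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as exc:
        raise RuntimeError(f"separation detected in logistic fit: {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 50:
        raise RuntimeError("logistic fit did not converge (possible separation)")
    beta = float(fit.params["low_copy"])
    se = float(fit.bse["low_copy"])
    return {
        "or_adjusted": math.exp(beta),
        "ci_low": math.exp(beta - 1.96 * se),
        "ci_high": math.exp(beta + 1.96 * se),
        "p_value": float(fit.pvalues["low_copy"]),
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "n": int(len(df)),
    }


def onset_analysis(
    subjects: Iterable[SubjectRecord],
    low_set: frozenset[int] | set[int] = LOW_SET_DEFAULT,
    early_cutoff_years: float = 1.0,
) -> dict:
    """Onset-lapse analyses among cases with a recorded lapse.

    (1) Mann-Whitney U comparing the lapse from first use to dependence
    between low- and high-copy cases (two-sided); (2) the lapse dichotomized
    into early (< cutoff) vs late (>= cutoff; exactly 1.0 year is late) and
    tested one-tailed for enrichment of low copies among early-onset cases.
    Cases with a missing lapse are dropped listwise here only.
    """
    df = _subject_frame(subjects)
    cases = df[(df.status == "case") & df.onset_years.notna()]
    low = cases["total_copies"].isin(low_set)
    onset_low = cases.loc[low, "onset_years"].to_numpy(float)
    onset_high = cases.loc[~low, "onset_years"].to_numpy(float)
    if len(onset_low) == 0 or len(onset_high) == 0:
        raise ValueError("a copy group has no cases with onset data")
    mw = mannwhitneyu(onset_low, onset_high, alternative="two-sided")
    early = cases["onset_years"] < early_cutoff_years
    counts = np.array(
        [
            [int((early & low).sum()), int((early & ~low).sum())],
            [int((~early & low).sum()), int((~early & ~low).sum())],
        ]
    )
    early_late = ContingencyTable(counts, ("early", "late"), ("low", "high"))
    fisher = fisher_exact_2x2(early_late, sidedness="one", alternative="greater")
    return {
        "mann_whitney_u": float(mw.statistic),
        "mann_whitney_p": float(mw.pvalue),
        "median_onset_low": float(np.median(onset_low)),
        "median_onset_high": float(np.median(onset_high)),
        "early_late_table": early_late,
        "one_tailed_fisher": fisher,
        "n_cases_with_onset": int(len(cases)),
    }
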