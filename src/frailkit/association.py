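"""Association statistics for scored cross-sectional cohorts.

The statistical layer of the analysis: covariate-by-severity contingency
tables with Pearson chi-square tests, within-level frailty odds and
conventional 2x2 odds ratios on the fit/frail collapse, binary logistic
regression with Wald intervals (unadjusted = one covariate at a time,
adjusted = all covariates jointly), the pooled two-sample t-test, the
Cronbach alpha reliability coefficient of the deficit items, and binomial
prevalence intervals.

Two odds conventions are exposed deliberately.  ``subgroup_frailty_odds``
returns the within-level odds frail/fit for a single covariate level —
the quantity survey reports often print as the "unadjusted OR" column —
while ``odds_ratio`` is the textbook reference-contrast estimator
(cross-product of the 2x2 table against a reference level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import (
    DegenerateTableError,
    DomainError,
    InfiniteOddsError,
    RankDeficiencyError,
    SeparationError,
    UndefinedAlphaError,
    ValidationError,
)
from .reference_cohort import CATEGORIES, LEVEL_ORDER, REFERENCE_CROSSTABS, REFERENCE_LEVELS

__all__ = [
    "CrossTab",
    "ChiSquareResult",
    "OddsResult",
    "LogisticTerm",
    "LogisticFit",
    "TTestResult",
    "ReliabilityResult",
    "PrevalenceCI",
    "crosstab",
    "chi_square",
    "subgroup_frailty_odds",
    "odds_ratio",
    "fit_logistic",
    "fit_univariable",
    "t_test",
    "cronbach_alpha",
    "prevalence_ci",
]

#: 97.5% normal quantile used for all Wald-type 95% intervals.
Z95 = 1.959964


@dataclass(frozen=True)
class CrossTab:
    """A covariate-level by severity-category count table."""

    covariate_name: str
    levels: tuple[str, ...]
    counts: np.ndarray  # shape (n_levels, 4), severity order FIT/MILD/MODERATE/SEVERE
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.levels), len(self.categories)):
            raise ValidationError(
                f"counts shape {c.shape} does not match {len(self.levels)} levels "
                f"x {len(self.categories)} categories"
            )
        if (c < 0).any():
            raise ValidationError("negative count in cross-tab")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def binary_counts(self) -> dict[str, tuple[int, int]]:
        """Collapse to (fit, frail) per level: fit = FIT+MILD, frail = MODERATE+SEVERE."""
        fit = self.counts[:, :2].sum(axis=1)
        frail = self.counts[:, 2:].sum(axis=1)
        return {lvl: (int(f), int(r)) for lvl, f, r in zip(self.levels, fit, frail)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.levels), columns=list(self.categories))
        df.index.name = self.covariate_name
        return df

    @classmethod
    def from_counts(
        cls, covariate_name: str, counts: Mapping[str, Sequence[int]]
    ) -> "CrossTab":
        levels = tuple(counts.keys())
        return cls(covariate_name, levels, np.array([counts[l] for l in levels]))

    @classmethod
    def from_reference(cls, covariate_name: str) -> "CrossTab":
        """The shipped reference-cohort table for one covariate."""
        return cls.from_counts(covariate_name, REFERENCE_CROSSTABS[covariate_name])


def crosstab(
    records: pd.DataFrame,
    covariate: str,
    level_order: Sequence[str] | None = None,
    category_column: str = "category",
) -> CrossTab:
    """Tabulate severity categories against one covariate's levels.

    ``records`` must carry a severity category column and the covariate
    column.  ``level_order`` fixes the row order and may declare levels not
    present in the data (included with zero counts); it defaults to the
    shipped data-dictionary order for known covariates, else the sorted
    observed levels.
    """
    if covariate not in records.columns:
        raise ValidationError(f"unknown covariate {covariate!r}")
    if level_order is None:
        level_order = LEVEL_ORDER.get(covariate)
    observed = records[covariate].astype(str)
    if level_order is None:
        level_order = sorted(observed.unique())
    else:
        extra = set(observed.unique()) - set(level_order)
        if extra:
            raise ValidationError(f"undeclared levels for {covariate!r}: {sorted(extra)}")
    counts = np.zeros((len(level_order), len(CATEGORIES)), dtype=int)
    if len(records):
        tab = pd.crosstab(observed, records[category_column].astype(str))
        for i, lvl in enumerate(level_order):
            for j, cat in enumerate(CATEGORIES):
                if lvl in tab.index and cat in tab.columns:
                    counts[i, j] = tab.at[lvl, cat]
    return CrossTab(covariate, tuple(level_order), counts)


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table."""

    statistic: float
    df: int
    p_value: float
    low_expected: bool  # any expected cell count below 5


def chi_square(table: CrossTab | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square on the full severity table, no continuity correction."""
    counts = table.counts if isinstance(table, CrossTab) else np.asarray(table)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError(
            "need at least 2 rows and 2 columns with positive marginals"
        )
    statistic, p, df, expected = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        low_expected=bool((expected < 5).any()),
    )


@dataclass(frozen=True)
class OddsResult:
    """A within-level odds or a reference-contrast odds ratio with its 95% CI."""

    kind: str  # "subgroup_odds" | "odds_ratio"
    level: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    reference_level: str | None = None


def subgroup_frailty_odds(table: CrossTab, level: str) -> OddsResult:
    """Within-level frailty odds frail/fit on the binary collapse.

    The 95% interval is the log-odds normal approximation
    exp(ln(odds) +/- 1.96 sqrt(1/frail + 1/fit)); the p-value is the
    two-sided Wald test of ln(odds) = 0.
    """
    binary = table.binary_counts()
    if level not in binary:
        raise ValidationError(f"level {level!r} not in table {table.covariate_name!r}")
    fit, frail = binary[level]
    if fit == 0 or frail == 0:
        raise InfiniteOddsError(level, frail, fit)
    odds = frail / fit
    se = math.sqrt(1 / frail + 1 / fit)
    z = math.log(odds) / se
    return OddsResult(
        kind="subgroup_odds",
        level=level,
        estimate=odds,
        ci_low=math.exp(math.log(odds) - Z95 * se),
        ci_high=math.exp(math.log(odds) + Z95 * se),
        p_value=2 * stats.norm.sf(abs(z)),
    )


def odds_ratio(
    table: CrossTab, level: str, reference: str, haldane: bool = False
) -> OddsResult:
    """Reference-contrast odds ratio on the fit/frail collapse with Woolf CI.

    ``haldane`` adds 0.5 to every cell when any cell is empty
    (Haldane–Anscombe correction); otherwise empty cells raise.
    """
    binary = table.binary_counts()
    for lvl in (level, reference):
        if lvl not in binary:
            raise ValidationError(f"level {lvl!r} not in table {table.covariate_name!r}")
    fit_l, frail_l = binary[level]
    fit_r, frail_r = binary[reference]
    cells = [frail_l, fit_l, frail_r, fit_r]
    if any(c == 0 for c in cells):
        if not haldane:
            raise ValidationError(
                f"zero cell in 2x2 table for {level!r} vs {reference!r}; "
                "enable the Haldane-Anscombe correction"
            )
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    est = (a * d) / (b * c)
    se = math.sqrt(sum(1 / x for x in cells))
    z = math.log(est) / se
    return OddsResult(
        kind="odds_ratio",
        level=level,
        estimate=est,
        ci_low=math.exp(math.log(est) - Z95 * se),
        ci_high=math.exp(math.log(est) + Z95 * se),
        p_value=2 * stats.norm.sf(abs(z)),
        reference_level=reference,
    )


@dataclass(frozen=True)
class LogisticTerm:
    """One indicator term of a logistic fit (reference rows carry no estimate)."""

    name: str
    level: str
    beta: float | None = None
    se: float | None = None
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    is_reference: bool = False


@dataclass(frozen=True)
class LogisticFit:
    """A fitted binary logistic model in odds-ratio form."""

    terms: tuple[LogisticTerm, ...]
    intercept: float
    converged: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int

    def term(self, name: str, level: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name and t.level == level:
                return t
        raise KeyError((name, level))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "covariate": t.name,
                    "level": t.level,
                    "beta": t.beta,
                    "se": t.se,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                    "reference": t.is_reference,
                }
            )
        return pd.DataFrame(rows)


def _design_matrix(
    records: pd.DataFrame,
    covariates: Sequence[str],
    references: Mapping[str, str],
    level_order: Mapping[str, Sequence[str]],
) -> tuple[np.ndarray, list[tuple[str, str]], list[tuple[str, str]]]:
    cols: list[np.ndarray] = [np.ones(len(records))]
    terms: list[tuple[str, str]] = []
    refs: list[tuple[str, str]] = []
    for cov in covariates:
        if cov not in records.columns:
            raise ValidationError(f"unknown covariate {cov!r}")
        values = records[cov].astype(str)
        levels = list(level_order.get(cov) or sorted(values.unique()))
        ref = references.get(cov, levels[0])
        if ref not in levels:
            raise ValidationError(f"reference {ref!r} is not a level of {cov!r}")
        refs.append((cov, ref))
        for lvl in levels:
            if lvl == ref:
                continue
            terms.append((cov, lvl))
            cols.append((values == lvl).to_numpy(dtype=float))
    return np.column_stack(cols), terms, refs


def _find_separating_term(
    X: np.ndarray, y: np.ndarray, terms: list[tuple[str, str]]
) -> str | None:
    for j, (cov, lvl) in enumerate(terms, start=1):
        on = X[:, j] == 1
        if on.any() and (y[on].min() == y[on].max()):
            return f"{cov}={lvl}"
    return None


def fit_logistic(
    records: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "frail",
    references: Mapping[str, str] | None = None,
    level_order: Mapping[str, Sequence[str]] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression with Wald intervals.

    Categorical covariates are expanded to indicator terms against their
    declared reference levels; the outcome column must be boolean (or 0/1)
    with both classes present.  The fit is Newton iteration on the
    log-likelihood (equivalently iteratively reweighted least squares),
    converged when the gradient norm drops below ``tol``; standard errors
    come from the inverse observed information, odds ratios are exp(beta)
    with 95% bounds exp(beta +/- 1.96 se) and two-sided normal p-values.
    """
    references = {**REFERENCE_LEVELS, **(references or {})}
    level_order = {**LEVEL_ORDER, **(level_order or {})}
    y = records[outcome].astype(float).to_numpy()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError("outcome must contain both classes coded 0/1")
    X, terms, refs = _design_matrix(records, covariates, references, level_order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"design matrix is rank deficient ({X.shape[1]} columns)"
        )
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        culprit = _find_separating_term(X, y, terms)
        raise SeparationError(
            "logistic likelihood is unbounded"
            + (f"; separating term: {culprit}" if culprit else "")
        ) from exc

    built: list[LogisticTerm] = []
    by_cov: dict[str, list[LogisticTerm]] = {}
    for j, (cov, lvl) in enumerate(terms, start=1):
        beta = float(res.params[j])
        se = float(res.bse[j])
        t = LogisticTerm(
            name=cov,
            level=lvl,
            beta=beta,
            se=se,
            odds_ratio=math.exp(beta),
            ci_low=math.exp(beta - Z95 * se),
            ci_high=math.exp(beta + Z95 * se),
            p_value=2 * stats.norm.sf(abs(beta / se)),
        )
        by_cov.setdefault(cov, []).append(t)
    for cov, ref in refs:
        built.append(LogisticTerm(name=cov, level=ref, is_reference=True))
        built.extend(by_cov.get(cov, []))
    return LogisticFit(
        terms=tuple(built),
        intercept=float(res.params[0]),
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        log_likelihood=float(res.llf),
        n_obs=len(y),
    )


def fit_univariable(
    records: pd.DataFrame,
    covariate: str,
    outcome: str = "frail",
    **kwargs,
) -> LogisticFit:
    """One-covariate logistic fit (the 'unadjusted' model for that covariate)."""
    return fit_logistic(records, [covariate], outcome=outcome, **kwargs)


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sided Student t-test for a mean difference."""

    t: float
    df: float
    p_value: float
    mean_diff: float


def t_test(
    group_a: Sequence[float] | tuple[int, float, float],
    group_b: Sequence[float] | tuple[int, float, float],
) -> TTestResult:
    """Two-sample pooled t-test; accepts raw vectors or (n, mean, sd) summaries."""

    def _summary(g) -> tuple[int, float, float]:
        if isinstance(g, tuple) and len(g) == 3 and isinstance(g[0], int):
            return g
        arr = np.asarray(g, dtype=float)
        if len(arr) < 2:
            raise ValidationError("each group needs at least 2 observations")
        return len(arr), float(arr.mean()), float(arr.std(ddof=1))

    na, ma, sa = _summary(group_a)
    nb, mb, sb = _summary(group_b)
    if na < 2 or nb < 2:
        raise ValidationError("each group needs at least 2 observations")
    if sa <= 0 or sb <= 0:
        raise ValidationError("each group needs positive standard deviation")
    res = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=float(na + nb - 2),
        p_value=float(res.pvalue),
        mean_diff=ma - mb,
    )


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha internal-consistency coefficient."""

    alpha: float
    n_items: int
    n_subjects: int


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> ReliabilityResult:
    """Cronbach's alpha over a subjects-by-items matrix of deficit weights.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    with sample (ddof=1) variances; no missing entries allowed.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need at least 2 subjects and 2 items")
    if np.isnan(X).any():
        raise ValidationError("item matrix must be complete (no missing entries)")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedAlphaError("total-score variance is zero")
    alpha = k / (k - 1) * (1 - item_var / total_var)
    return ReliabilityResult(alpha=float(alpha), n_items=k, n_subjects=X.shape[0])


@dataclass(frozen=True)
class PrevalenceCI:
    """A binomial point estimate with its 95% confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    method: str


def prevalence_ci(k: int, n: int, method: str = "wilson") -> PrevalenceCI:
    """Prevalence k/n with a 95% interval (Wilson score by default, Wald optional)."""
    if n <= 0 or not 0 <= k <= n:
        raise DomainError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if method not in ("wilson", "wald"):
        raise ValidationError(f"unknown interval method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="normal" if method == "wald" else "wilson")
    return PrevalenceCI(
        estimate=k / n, ci_low=float(lo), ci_high=float(hi), k=k, n=n, method=method
    )
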