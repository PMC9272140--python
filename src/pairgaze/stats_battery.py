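"""The statistical battery: rank tests, chi-square, factorial ANOVA, Tukey HSD
and Pearson correlation.  Every reported p is two-tailed.

Small samples get exact null distributions — the signed-rank statistic by a
generating-function convolution over sign patterns (n <= 25), the rank-sum
statistic by enumeration of rank assignments (min group size <= 10) — and
larger samples the classic normal approximations with tie corrections.
Factorial ANOVA uses type-II sums of squares (each effect adjusted for all
terms not containing it), which keeps main effects interpretable in the
near-balanced designs this pipeline produces.  Tukey's HSD adjusts pairwise
comparisons with the studentized-range distribution (Tukey-Kramer for unequal
group sizes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_SIGNED_RANK_N = 25
EXACT_RANK_SUM_MIN_N = 10


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float  # two-tailed
    df: object = None  # int, tuple, or None
    n: object = None
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p = {self.p} outside [0, 1]")

    def renamed(self, name: str) -> "TestResult":
        from dataclasses import replace

        return replace(self, test=name)


def _two_sided_from_cdf(p_le: float, p_ge: float) -> float:
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@lru_cache(maxsize=512)
def _signed_rank_pmf(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Null pmf of 2W (W = positive-rank sum) over all 2^n sign patterns.

    Midranks are doubled so every rank is integral; entry k of the result is
    the number of sign patterns with 2W = k, normalised to sum 1.
    """
    pmf = np.array([1.0])
    for r in doubled_ranks:
        shifted = np.concatenate([np.zeros(r), pmf])
        if len(pmf) < len(shifted):
            pmf = np.concatenate([pmf, np.zeros(len(shifted) - len(pmf))])
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Paired-sample signed-rank test on a vector of differences.

    Zero differences are dropped first (Wilcoxon's convention); W is the sum
    of the ranks of the positive differences, ranked by absolute value with
    midranks for ties.  Exact two-tailed p for n <= 25, otherwise a normal
    approximation whose variance term sum(r_i^2)/4 is tie-exact.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_N:
        doubled = tuple(sorted(int(round(2 * r)) for r in ranks))
        pmf = _signed_rank_pmf(doubled)
        k = int(round(2 * w))
        p_le = float(pmf[: k + 1].sum())
        p_ge = float(pmf[k:].sum())
        p = _two_sided_from_cdf(p_le, p_ge)
        method = "exact (sign-pattern enumeration)"
    else:
        mean = float(ranks.sum()) / 2.0
        var = float((ranks**2).sum()) / 4.0
        delta = abs(w - mean)
        z = max(0.0, delta - 0.5) / math.sqrt(var)  # continuity correction
        p = min(1.0, 2.0 * stats.norm.sf(z))
        method = "normal approximation, tie-exact variance, continuity-corrected"
    return TestResult(test="wilcoxon_signed_rank", statistic=w, p=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)


def wilcoxon_rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Unpaired two-sample rank-sum test; statistic is Mann-Whitney U for
    sample_a.  Exact p by enumeration of rank assignments when the smaller
    group has <= 10 observations (and the enumeration stays modest),
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    n = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = float(ranks[:na].sum())
    u_a = r_a - na * (na + 1) / 2.0
    exact_feasible = min(na, nb) <= EXACT_RANK_SUM_MIN_N and math.comb(n, na) <= 500_000
    if exact_feasible:
        rank_tuple = tuple(ranks)
        target = round(2 * r_a)
        count_le = count_ge = total = 0
        for combo in itertools.combinations(rank_tuple, na):
            s = round(2 * sum(combo))
            total += 1
            if s <= target:
                count_le += 1
            if s >= target:
                count_ge += 1
        p = _two_sided_from_cdf(count_le / total, count_ge / total)
        method = "exact (rank-assignment enumeration)"
    else:
        mean = na * nb / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return TestResult(
                test="wilcoxon_rank_sum", statistic=u_a, p=1.0, n=(na, nb),
                method="degenerate (all values tied)",
            )
        z = (u_a - mean - math.copysign(0.5, u_a - mean)) / math.sqrt(var) if u_a != mean else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        method = "normal approximation with tie and continuity correction"
    return TestResult(test="wilcoxon_rank_sum", statistic=u_a, p=min(1.0, p), n=(na, nb), method=method)


# ---------------------------------------------------------------------------
# Chi-square


def chi2_proportion(successes: int, n: int, null_p: float = 0.5) -> TestResult:
    """Pearson chi-square of an observed proportion against a null value."""
    if n <= 0:
        raise ValueError("n must be positive")
    expected = np.array([n * null_p, n * (1 - null_p)])
    if (expected < 1).any():
        raise ValueError("expected count < 1; use an exact binomial test instead")
    observed = np.array([successes, n - successes], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(
        test="chi2_proportion", statistic=chi2, p=float(stats.chi2.sf(chi2, 1)), df=1, n=n,
        method="Pearson chi-square, df=1",
    )


def chi2_contingency(table: np.ndarray) -> TestResult:
    """Pearson chi-square of independence on an r x k contingency table."""
    table = np.asarray(table, dtype=float)
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        raise ValueError("expected count < 1; use an exact test instead")
    return TestResult(
        test="chi2_contingency", statistic=float(chi2), p=float(p), df=int(df),
        n=int(table.sum()), method="Pearson chi-square of independence",
    )


# ---------------------------------------------------------------------------
# Factorial ANOVA (type-II sums of squares)


def _dummy_columns(labels: np.ndarray) -> tuple[np.ndarray, int]:
    levels = np.unique(labels)
    cols = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 else np.empty((len(labels), 0))
    return cols, len(levels)


def _term_design(factor_cols: dict[str, np.ndarray], term: tuple[str, ...]) -> np.ndarray:
    design = None
    for f in term:
        cols = factor_cols[f]
        if design is None:
            design = cols
        else:
            design = np.stack(
                [design[:, i] * cols[:, j] for i in range(design.shape[1]) for j in range(cols.shape[1])],
                axis=1,
            )
    return design


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(((y - fitted) ** 2).sum())


def anova_factorial(
    values: Sequence[float],
    factors: dict[str, Sequence] | pd.DataFrame,
    include_interactions: bool = True,
) -> list[TestResult]:
    """Factorial ANOVA (1-3 factors) with type-II sums of squares.

    Each effect's SS is the residual-SS drop from adding it to the model that
    already contains every term not containing it; F uses the full-model
    residual mean square.  Works on unbalanced cell counts; an empty cell
    (with interactions requested) is an error naming the cell.
    """
    y = np.asarray(values, dtype=float)
    if isinstance(factors, pd.DataFrame):
        factors = {c: factors[c].to_numpy() for c in factors.columns}
    names = list(factors.keys())
    if not 1 <= len(names) <= 3:
        raise ValueError("anova_factorial supports 1-3 factors")
    labels = {f: np.asarray(v) for f, v in factors.items()}
    for f, v in labels.items():
        if len(v) != len(y):
            raise ValueError(f"factor {f!r} length mismatch")
        if len(np.unique(v)) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    if include_interactions and len(names) > 1:
        combos = itertools.product(*[np.unique(labels[f]) for f in names])
        stacked = np.stack([labels[f] for f in names], axis=1)
        for combo in combos:
            if not (stacked == np.array(combo, dtype=stacked.dtype)).all(axis=1).any():
                cell = ", ".join(f"{f}={v}" for f, v in zip(names, combo))
                raise ValueError(f"empty cell ({cell}) makes interaction effects inestimable")

    factor_cols = {}
    n_levels = {}
    for f in names:
        cols, k = _dummy_columns(labels[f])
        factor_cols[f] = cols
        n_levels[f] = k
    terms: list[tuple[str, ...]] = [(f,) for f in names]
    if include_interactions:
        for order in range(2, len(names) + 1):
            terms.extend(itertools.combinations(names, order))

    def build(term_set: list[tuple[str, ...]]) -> np.ndarray:
        blocks = [np.ones((len(y), 1))]
        blocks += [_term_design(factor_cols, t) for t in term_set]
        return np.concatenate(blocks, axis=1)

    X_full = build(terms)
    rss_full = _rss(X_full, y)
    df_resid = len(y) - np.linalg.matrix_rank(X_full)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    results = []
    for term in terms:
        others = [s for s in terms if not set(term) <= set(s)]
        rss_without = _rss(build(others), y)
        rss_with = _rss(build(others + [term]), y)
        df_term = 1
        for f in term:
            df_term *= n_levels[f] - 1
        ss = max(0.0, rss_without - rss_with)  # clamp numerical noise
        total = float(((y - y.mean()) ** 2).sum())
        tiny = 1e-12 * max(total, 1.0)
        if rss_full <= tiny:  # saturated fit: no residual variance
            f_stat = math.inf if ss > tiny else 0.0
        else:
            f_stat = (ss / df_term) / (rss_full / df_resid)
        p = float(stats.f.sf(f_stat, df_term, df_resid))
        results.append(
            TestResult(
                test="anova[" + ":".join(term) + "]",
                statistic=float(f_stat),
                p=p,
                df=(df_term, df_resid),
                n=len(y),
                method="type-II SS factorial ANOVA",
            )
        )
    return results


# ---------------------------------------------------------------------------
# Tukey HSD


def tukey_hsd(values: Sequence[float], groups: Sequence) -> pd.DataFrame:
    """Pairwise Tukey-Kramer comparisons after a one-way ANOVA.

    Returns one row per pair with the mean difference and the adjusted p from
    the studentized-range distribution on (k groups, residual df).  With two
    groups this degenerates to the unadjusted two-sample t-test.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = list(np.unique(g))
    k = len(levels)
    if k < 2:
        raise ValueError("tukey_hsd needs >= 2 groups")
    ns = {lv: int((g == lv).sum()) for lv in levels}
    means = {lv: float(y[g == lv].mean()) for lv in levels}
    df_resid = len(y) - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    sse = sum(float(((y[g == lv] - means[lv]) ** 2).sum()) for lv in levels)
    mse = sse / df_resid
    rows = []
    for lv1, lv2 in itertools.combinations(levels, 2):
        diff = means[lv2] - means[lv1]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[lv1] + 1.0 / ns[lv2]))
        if se == 0:
            q_obs, p_adj = (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
        else:
            q_obs = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q_obs, k, df_resid))
        rows.append(
            {"group1": lv1, "group2": lv2, "mean_diff": diff, "q": q_obs, "p_adj": min(1.0, p_adj)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pearson correlation


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation with a two-tailed t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("pearson_r needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r requires nonzero variance in both variables")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        test="pearson_r", statistic=float(r), p=float(p), df=len(x) - 2, n=len(x),
        method="t-transform, n-2 df",
    )


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "df": [str(r.df) for r in results],
            "n": [str(r.n) for r in results],
            "method": [r.method for r in results],
        }
    )
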