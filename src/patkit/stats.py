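"""Group-comparison battery for the cohort analyses.

Implements the tests as the pipeline applies them: Student pooled-variance
t (df = n_a + n_b - 2), Pearson chi-squared with all-zero categories
dropped and no continuity correction, Mann-Whitney rank-sum with
tie-corrected normal approximation reporting |Z|, Spearman's rho with the
t approximation, OLS residualization, one-way ANOVA, and analytic power
of the two-sided pooled t via the noncentral t distribution. All p-values
are two-tailed; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    test: str
    statistic: float
    df: Optional[float]
    p_value: float
    groups: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "groups": self.groups,
            **({"extra": self.extra} if self.extra else {}),
        }


def _describe(name: str, x: np.ndarray) -> dict:
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "group": name,
    }


def pooled_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    names: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Student two-sample t with pooled variance; positive t means
    group_a's mean exceeds group_b's."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    t = float((a.mean() - b.mean()) / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(
        test="pooled_t",
        statistic=t,
        df=float(df),
        p_value=p,
        groups={names[0]: _describe(names[0], a), names[1]: _describe(names[1], b)},
    )


def chisq_test(table: Sequence[Sequence[float]], drop_empty: bool = True) -> GroupComparison:
    """Pearson X^2 on an r x c count table, no continuity correction.

    All-zero rows/columns are removed first (an empty evidence category
    carries no information and would make expected counts zero); df is
    computed on the reduced table.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if drop_empty:
        obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("reduced table must be at least 2x2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(x2, df))
    return GroupComparison(
        test="chisq",
        statistic=x2,
        df=float(df),
        p_value=p,
        extra={"reduced_shape": list(obs.shape), "n": int(obs.sum())},
    )


def rank_sum_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    names: tuple[str, str] = ("a", "b"),
    continuity: bool = False,
) -> GroupComparison:
    """Mann-Whitney U with tie-corrected normal approximation.

    The reported statistic is |Z| (its sign, positive when group_a ranks
    higher, is kept in ``extra``). Continuity correction is off by
    default.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs n >= 1")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # U for group_a
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        raise ValueError("all values tied across both groups")
    num = u1 - mu
    if continuity and num != 0:
        num -= 0.5 * np.sign(num)
    z = float(num / np.sqrt(var))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return GroupComparison(
        test="rank_sum",
        statistic=abs(z),
        df=None,
        p_value=p,
        groups={names[0]: _describe(names[0], a), names[1]: _describe(names[1], b)},
        extra={"u": float(u1), "z_signed": z},
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Spearman rank correlation (mid-ranks) with two-tailed t-approximation p."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(xa, ya)
    return GroupComparison(
        test="spearman",
        statistic=float(rho),
        df=float(xa.size - 2),
        p_value=float(p),
    )


def residualize(y: Sequence[float], covariates: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """OLS residuals of y on an intercept plus the given covariate columns."""
    yv = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(yv.size), np.asarray(covariates, dtype=float).reshape(yv.size, -1)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    return yv - X @ beta


def oneway_anova(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """One-way fixed-effects ANOVA, F(k-1, N-k)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(arrs)
    n = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("no variance anywhere")
        f = float("inf")
        p = 0.0
    else:
        f = float((ss_between / df1) / (ss_within / df2))
        p = float(sps.f.sf(f, df1, df2))
    return GroupComparison(
        test="oneway_anova",
        statistic=f,
        df=float(df1),
        p_value=p,
        extra={"df_within": float(df2)},
    )


def power_two_sample(d: float, n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Power of the two-sided pooled two-sample t at effect size d.

    Uses the noncentral t with ncp = d * sqrt(n_a*n_b/(n_a+n_b)).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    df = n_a + n_b - 2
    ncp = d * np.sqrt(n_a * n_b / (n_a + n_b))
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
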