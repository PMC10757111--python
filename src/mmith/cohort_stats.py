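"""Cohort-level statistics: splits, rank correlations, two-group tests,
contingency tests, Kaplan-Meier/log-rank, and Cox proportional hazards.

Thin, contract-enforcing wrappers over scipy.stats and lifelines. All tests
are two-sided. The 2x2 chi-square is deliberately the uncorrected Pearson
statistic (no Yates continuity correction) — the convention used for the
remission-rate comparison this pipeline reproduces. Median splits send ties
at the median to the low group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    effect: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise DomainError(f"p-value {self.p_value} outside [0,1]")


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    hazard_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass(frozen=True)
class SurvivalFit:
    covariates: list[CovariateEffect]
    n: int
    n_events: int
    converged: bool
    log_likelihood: float


def median_split(values: Mapping[Hashable, float]) -> tuple[list, list]:
    """Split keys into (low, high) by the cohort median; ties go low."""
    if len(values) < 2:
        raise DomainError("median_split needs at least two patients")
    med = float(np.median(list(values.values())))
    low = [k for k, v in values.items() if v <= med]
    high = [k for k, v in values.items() if v > med]
    return low, high


def _check_paired(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired samples must be equal-length 1-D arrays")
    if x.size < min_n:
        raise DomainError(f"need at least {min_n} pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DomainError("constant input: rank correlation undefined")
    return x, y


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall tau-b with tie correction; exact p for small n (scipy default)."""
    x, y = _check_paired(x, y)
    res = stats.kendalltau(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect=float(res.statistic),
        method="kendall_tau_b",
        n=int(x.size),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with midrank ties; two-sided p."""
    x, y = _check_paired(x, y)
    res = stats.spearmanr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect=float(res.statistic),
        method="spearman_rho",
        n=int(x.size),
    )


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum.

    Exact null distribution when both samples are small and untied,
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon_rank_sum[{method}]",
        n=int(a.size + b.size),
        effect=float(np.median(a) - np.median(b)),
    )


def chi_square_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table, df=1, two-sided.

    Also reports each row's first-column proportion (e.g. response rate per
    group) in ``extra['proportions']``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DomainError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DomainError("zero margin: chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    props = (t[:, 0] / t.sum(axis=1)).tolist()
    return TestResult(
        statistic=float(chi2),
        p_value=float(p),
        method="pearson_chi2_uncorrected",
        n=int(t.sum()),
        effect=float(props[1] - props[0]),
        extra={"proportions": props},
    )


def km_logrank(
    groups: Mapping[str, Sequence[tuple[float, bool]]],
) -> tuple[TestResult, dict[str, pd.DataFrame]]:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    *groups* maps a label to (time, event) records. Returns the test and a
    per-group survival step function (``timeline``/``survival`` columns).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    if len(groups) < 2:
        raise DomainError("log-rank needs at least two groups")
    curves: dict[str, pd.DataFrame] = {}
    parsed = {}
    for label, recs in groups.items():
        if len(recs) == 0:
            raise DomainError(f"group {label!r} has no subjects")
        t = np.asarray([r[0] for r in recs], dtype=float)
        e = np.asarray([bool(r[1]) for r in recs])
        if np.any(t < 0):
            raise DomainError("survival times must be >= 0")
        parsed[label] = (t, e)
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e, label=str(label))
        curves[label] = pd.DataFrame(
            {
                "timeline": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
    labels = list(parsed)
    if len(labels) == 2:
        (t1, e1), (t2, e2) = parsed[labels[0]], parsed[labels[1]]
        res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    else:
        t_all = np.concatenate([parsed[l][0] for l in labels])
        g_all = np.concatenate([[l] * len(parsed[l][0]) for l in labels])
        e_all = np.concatenate([parsed[l][1] for l in labels])
        res = multivariate_logrank_test(t_all, g_all, e_all)
    n = sum(len(v) for v in parsed.values())
    return (
        TestResult(
            statistic=float(res.test_statistic),
            p_value=float(res.p_value),
            method="logrank",
            n=n,
        ),
        curves,
    )


def cox_ph(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
) -> SurvivalFit:
    """Multivariate Cox PH via partial likelihood (Efron tie handling).

    Returns per-covariate hazard ratios with Wald 95% CIs and p-values.
    Separation or non-convergence yields a flagged result, not a crash.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cov = pd.DataFrame(covariates).reset_index(drop=True)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(cov) != t.size or t.size != e.size:
        raise DomainError("covariates, times and events must align")
    if len(cov) <= cov.shape[1]:
        raise DomainError("need more subjects than covariates")
    for c in cov.columns:
        if cov[c].nunique() <= 1:
            raise DomainError(f"constant covariate {c!r}")
    df = cov.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        return SurvivalFit(
            covariates=[
                CovariateEffect(c, np.nan, np.nan, np.nan, np.nan) for c in cov.columns
            ],
            n=int(t.size),
            n_events=int(e.sum()),
            converged=False,
            log_likelihood=np.nan,
        )
    summ = cph.summary
    effects = [
        CovariateEffect(
            name=str(idx),
            hazard_ratio=float(row["exp(coef)"]),
            ci95_low=float(row["exp(coef) lower 95%"]),
            ci95_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        )
        for idx, row in summ.iterrows()
    ]
    return SurvivalFit(
        covariates=effects,
        n=int(t.size),
        n_events=int(e.sum()),
        converged=converged,
        log_likelihood=float(cph.log_likelihood_),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test across two or more groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DomainError("ANOVA needs >= 2 groups each with >= 2 observations")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # no variance anywhere: F is 0/0; report the degenerate null result
        return TestResult(statistic=0.0, p_value=1.0, method="one_way_anova", n=pooled.size)
    if all(np.var(a) == 0 for a in arrays) and len({a[0] for a in arrays}) > 1:
        raise DomainError("zero within-group variance with distinct means: F undefined")
    f, p = stats.f_oneway(*arrays)
    return TestResult(
        statistic=float(f), p_value=float(p), method="one_way_anova", n=int(pooled.size)
    )
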