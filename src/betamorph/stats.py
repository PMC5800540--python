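"""Method-comparison statistics for beta-cell volume studies.

Covers the analysis set used to compare fully automatic against
investigator-corrected morphometry: group summaries and fold changes, the
2x2 factorial ANOVA (condition x analysis method, Type-III tests with
sum-to-zero coding, robust to the unbalanced n = 10 vs 12 design), classic
one-way and Welch ANOVA, mean-centered Levene's test for equality of
variances, and exact two-sample t-test power / sample size via the
noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import ConfigurationError

__all__ = [
    "PowerSpec",
    "AnovaResult",
    "summarize",
    "factorial_anova_2x2",
    "one_way_anova",
    "welch_anova",
    "welch_anova_from_summary",
    "levene_test",
    "power_two_means",
    "sample_size_two_means",
]

_EPS = 1e-12


@dataclass
class TermTest:
    F: float
    df_num: float
    df_den: float
    p: float
    t: Optional[float] = None  # signed t ratio for single-df terms


@dataclass
class AnovaResult:
    """F tests per term plus (for factorial fits) the whole-model test."""

    terms: Dict[str, TermTest]
    model: Optional[TermTest] = None
    degenerate: bool = False

    def term(self, name: str) -> TermTest:
        return self.terms[name]


@dataclass
class PowerSpec:
    """Design of a two-sample t-test power question.

    ``delta`` is the true mean difference (mm^3), ``sd`` the common standard
    deviation (mm^3); rejection at level ``alpha``, two-sided by default.
    """

    delta: float
    sd: float
    alpha: float = 0.05
    target_power: float = 0.80
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError("sd must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not (0.0 < self.target_power < 1.0):
            raise ConfigurationError("target_power must lie in (0, 1)")


# ---------------------------------------------------------------------------
# summaries


def summarize(table: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per (condition, method) n / mean / SD, plus PDL/Sham fold per method.

    SD is the sample (n-1) standard deviation. Raises if any populated group
    has fewer than 2 observations.
    """
    required = {"condition", "method", "volume_mm3"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"study table needs columns {sorted(required)}")
    grouped = table.groupby(["condition", "method"], observed=True)["volume_mm3"]
    summary = grouped.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    if (summary["n"] < 2).any():
        bad = summary.index[summary["n"] < 2].tolist()
        raise ConfigurationError(f"groups with n < 2: {bad}")
    summary = summary.reset_index()
    folds: Dict[str, float] = {}
    for method, sub in summary.groupby("method", observed=True):
        means = dict(zip(sub["condition"], sub["mean"]))
        if "PDL" in means and "Sham" in means:
            folds[str(method)] = float(means["PDL"] / means["Sham"])
    return summary, folds


# ---------------------------------------------------------------------------
# ANOVA family


def factorial_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """2x2 factorial ANOVA of volume on condition, method, and interaction.

    Least-squares fit with sum-to-zero (effect) coding and Type-III tests,
    appropriate for the unbalanced design. Terms are reported as
    ``condition``, ``method`` and ``condition:method``; single-df terms carry
    their signed t ratio. The whole-model F compares the full fit against
    the intercept-only fit. A term (or the model) with zero sum of squares
    under zero residual variance reports F = 0.
    """
    counts = table.groupby(["condition", "method"], observed=True).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ConfigurationError(
            "factorial ANOVA needs all four condition x method cells with n >= 2"
        )
    df = table.copy()
    fit = smf.ols(
        "volume_mm3 ~ C(condition, Sum) * C(method, Sum)", data=df
    ).fit()
    aov = sm.stats.anova_lm(fit, typ=3)

    name_map = {
        "C(condition, Sum)": "condition",
        "C(method, Sum)": "method",
        "C(condition, Sum):C(method, Sum)": "condition:method",
    }
    zero_resid = fit.ssr < _EPS
    df_resid = float(fit.df_resid)
    terms: Dict[str, TermTest] = {}
    terms_t: Dict[str, float] = {}
    for pname, tval in fit.tvalues.items():
        if pname == "Intercept":
            continue
        if ":" in pname:
            terms_t["condition:method"] = float(tval)
        elif pname.startswith("C(condition"):
            terms_t["condition"] = float(tval)
        elif pname.startswith("C(method"):
            terms_t["method"] = float(tval)
    for raw, nice in name_map.items():
        ss = float(aov.loc[raw, "sum_sq"])
        dfn = float(aov.loc[raw, "df"])
        if zero_resid:
            F = 0.0 if ss < _EPS else float("inf")
            p = 1.0 if ss < _EPS else 0.0
        else:
            F = float(aov.loc[raw, "F"])
            p = float(aov.loc[raw, "PR(>F)"])
        terms[nice] = TermTest(F=F, df_num=dfn, df_den=df_resid, p=p,
                               t=terms_t.get(nice))
    if zero_resid:
        ess = float(fit.ess)
        model = TermTest(
            F=0.0 if ess < _EPS else float("inf"),
            df_num=float(fit.df_model),
            df_den=df_resid,
            p=1.0 if ess < _EPS else 0.0,
        )
    else:
        model = TermTest(
            F=float(fit.fvalue),
            df_num=float(fit.df_model),
            df_den=df_resid,
            p=float(fit.f_pvalue),
        )
    return AnovaResult(terms=terms, model=model, degenerate=zero_resid)


def _as_groups(groups: Sequence[Sequence[float]]) -> List[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ConfigurationError("need >= 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ConfigurationError(f"group {i} has n < 2")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic (pooled-variance) one-way ANOVA.

    For two groups, F equals the square of the pooled two-sample t
    statistic. All-zero within-group variance with equal means is reported
    as degenerate (F = 0, p = 1).
    """
    gs = _as_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    dfb, dfw = k - 1, n_total - k
    if ssw < _EPS:
        if ssb < _EPS:
            term = TermTest(F=0.0, df_num=dfb, df_den=dfw, p=1.0)
            return AnovaResult(terms={"group": term}, degenerate=True)
        term = TermTest(F=float("inf"), df_num=dfb, df_den=dfw, p=0.0)
        return AnovaResult(terms={"group": term}, degenerate=True)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(terms={"group": TermTest(F=float(F), df_num=dfb, df_den=dfw, p=p)})


def welch_anova_from_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> AnovaResult:
    """Welch's heteroscedastic F test from group summary statistics.

    Uses the Welch (1951) statistic with Welch–Satterthwaite denominator
    degrees of freedom; for two groups it equals the square of Welch's t.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.size == sds.size == ns.size) or means.size < 2:
        raise ConfigurationError("need matching means/sds/ns for >= 2 groups")
    if (ns < 2).any():
        raise ConfigurationError("every group needs n >= 2")
    if (sds <= 0).all():
        term = TermTest(F=0.0, df_num=means.size - 1, df_den=float("nan"), p=1.0)
        return AnovaResult(terms={"group": term}, degenerate=True)
    k = means.size
    w = ns / sds**2
    sw = w.sum()
    mw = (w * means).sum() / sw
    a = (w * (means - mw) ** 2).sum() / (k - 1)
    lam = ((1.0 - w / sw) ** 2 / (ns - 1.0)).sum()
    F = a / (1.0 + 2.0 * (k - 2.0) / (k**2 - 1.0) * lam)
    df1 = k - 1.0
    df2 = (k**2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(
        terms={"group": TermTest(F=float(F), df_num=df1, df_den=float(df2), p=p)}
    )


def welch_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    gs = _as_groups(groups)
    return welch_anova_from_summary(
        [g.mean() for g in gs], [g.std(ddof=1) for g in gs], [g.size for g in gs]
    )


def levene_test(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic (mean-centered) Levene test for equality of variances.

    Definitionally a one-way ANOVA on the absolute deviations from each
    group's mean.
    """
    gs = _as_groups(groups)
    deviations = [np.abs(g - g.mean()) for g in gs]
    return one_way_anova(deviations)


# ---------------------------------------------------------------------------
# power / sample size (noncentral t)


def power_two_means(n1: int, n2: int, spec: PowerSpec) -> float:
    """Exact power of the two-sample t test via the noncentral t.

    df = n1 + n2 - 2; noncentrality delta / (sd * sqrt(1/n1 + 1/n2)). For a
    two-sided test the (tiny) lower-tail rejection probability is included.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("n1 and n2 must be >= 2")
    df = n1 + n2 - 2
    ncp = abs(spec.delta) / (spec.sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    if spec.two_sided:
        tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
        power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = sps.t.ppf(1.0 - spec.alpha, df)
        power = sps.nct.sf(tcrit, df, ncp)
    return float(power)


def sample_size_two_means(
    spec: PowerSpec, n_max: int = 1_000_000
) -> Tuple[int, int]:
    """Smallest balanced per-group n reaching the target power.

    Returns ``(n_per_group, n_total)`` with ``n_total = 2 * n_per_group``,
    searching upward from n = 2.
    """
    if spec.delta == 0:
        raise ConfigurationError("delta must be nonzero for a sample size search")
    n = 2
    while power_two_means(n, n, spec) < spec.target_power:
        n += 1
        if n > n_max:
            raise ConfigurationError("sample size search exceeded n_max")
    return n, 2 * n
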