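"""The small statistics layer the other modules call.

Exact 2x2 test, two-sided variance-ratio (F) test, t-test / one-way
ANOVA with Tukey HSD, ordinary least squares with formula support and
interactions, and comparative-Ct relative expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FisherResult",
    "FTestResult",
    "GroupCompareResult",
    "LinearModelFit",
    "fisher_exact_2x2",
    "variance_f_test",
    "group_compare",
    "linear_model",
    "comparative_ct",
]


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    alternative: str


def fisher_exact_2x2(table, alternative: str = "two-sided") -> FisherResult:
    """Fisher's exact test on a 2x2 contingency table.

    Exact hypergeometric enumeration; the two-sided p-value sums the
    probabilities of all tables (same margins) no more probable than the
    observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise ValueError("counts must be nonnegative integers")
    t = t.astype(np.int64)
    if t.sum() == 0:
        raise ValueError("table total must be > 0")
    odds, p = sps.fisher_exact(t, alternative=alternative)
    return FisherResult(p_value=float(p), odds_ratio=float(odds), alternative=alternative)


@dataclass(frozen=True)
class FTestResult:
    f: float
    p_value: float
    df1: int
    df2: int


def variance_f_test(a, b) -> FTestResult:
    """Two-sided F-test for equality of two normal variances.

    F = s_a^2 / s_b^2 (sample variances); p = 2 * min(P(F' <= F),
    P(F' >= F)) under F(n_a - 1, n_b - 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if vb == 0:
        raise ValueError("denominator sample has zero variance")
    f = va / vb
    df1, df2 = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, df1, df2)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return FTestResult(f=f, p_value=p, df1=df1, df2=df2)


@dataclass(frozen=True)
class GroupCompareResult:
    method: str
    statistic: float
    p_value: float
    pairwise: Optional[pd.DataFrame] = None  # Tukey HSD table for ANOVA


def group_compare(groups, method: str = "t", welch: bool = True) -> GroupCompareResult:
    """Two-sided t-test (Welch by default) or one-way ANOVA + Tukey HSD.

    ``groups`` is a sequence of samples, or a mapping name -> sample.
    """
    if isinstance(groups, Mapping):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(samples))]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least 2 values")
    if method == "t":
        if len(samples) != 2:
            raise ValueError("t-test compares exactly 2 groups")
        t, p = sps.ttest_ind(samples[0], samples[1], equal_var=not welch)
        return GroupCompareResult(method="welch_t" if welch else "pooled_t",
                                  statistic=float(t), p_value=float(p))
    if method == "anova_tukey":
        if len(samples) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        f, p = sps.f_oneway(*samples)
        values = np.concatenate(samples)
        labels = np.concatenate([[n] * s.size for n, s in zip(names, samples)])
        tk = pairwise_tukeyhsd(values, labels)
        pairwise = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        return GroupCompareResult(method="anova_tukey", statistic=float(f),
                                  p_value=float(p), pairwise=pairwise)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class LinearModelFit:
    """OLS fit summary (formula interface, factors and interactions
    supported)."""

    formula: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    rsquared: float
    df_resid: int
    nobs: int


def linear_model(data: pd.DataFrame, formula: str) -> LinearModelFit:
    """Ordinary least squares via an R-style formula (e.g.
    ``"f ~ ti + te"`` or ``"vo2 ~ genotype * cold"``).

    Rank-deficient designs are rejected with the aliased columns named;
    non-finite values in used columns are rejected.
    """
    numeric = data.select_dtypes(include=[np.number])
    if not np.all(np.isfinite(numeric.to_numpy(dtype=float))):
        bad = [c for c in numeric.columns
               if not np.all(np.isfinite(numeric[c].to_numpy(dtype=float)))]
        raise ValueError(f"non-finite values in column(s) {bad}")
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name aliased columns via pivoted QR (small diagonal of R)
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [model.exog_names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")
    if exog.shape[0] <= exog.shape[1]:
        raise ValueError("need more observations than parameters")
    fit = model.fit()
    ci = fit.conf_int()
    ci.columns = ["low", "high"]
    return LinearModelFit(
        formula=formula,
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        conf_int=ci,
        rsquared=float(fit.rsquared),
        df_resid=int(fit.df_resid),
        nobs=int(fit.nobs),
    )


def comparative_ct(ct_target, ct_reference, calibrator_delta: float = 0.0):
    """Relative expression by the comparative-Ct method.

    delta-Ct = Ct_target - Ct_reference; delta-delta-Ct = delta-Ct -
    calibrator_delta; relative expression = 2 ** (-delta-delta-Ct).
    Accepts scalars or arrays.
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_r))
            and np.isfinite(calibrator_delta)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_t - ct_r) - calibrator_delta
    rel = 2.0 ** (-ddct)
    return float(rel) if rel.ndim == 0 else rel
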