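"""Regression and hypothesis-testing utilities.

Covers the statistics used around the network models: ordinary
least-squares fits of observed on predicted abundance with standard
errors, a Wald-type t-test of a fitted slope/intercept against its
theoretical value (1 and 0 for a perfect model), the pooled two-sample
Student's t-test used to contrast the seasonal and spatial datasets, a
bidirectional stepwise multiple linear regression (SMLR) baseline, and
published-table-style column summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionFit",
    "SMLRModel",
    "linfit",
    "t_vs_theory",
    "two_sample_t",
    "smlr",
    "summarize",
]


@dataclass
class RegressionFit:
    """Simple OLS fit y = intercept + slope * x with uncertainty."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r2: float
    n: int
    residual_sd: float


def linfit(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """Ordinary least-squares line with standard errors; r^2 is the
    squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("predictor has zero variance; fit is degenerate")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if syy == 0.0 else sxy**2 / (sxx * syy)
    return RegressionFit(
        intercept=intercept,
        slope=float(slope),
        se_intercept=float(se_intercept),
        se_slope=float(se_slope),
        r2=float(r2),
        n=int(n),
        residual_sd=float(np.sqrt(s2)),
    )


def t_vs_theory(
    fit: RegressionFit, which: str, theoretical: float
) -> tuple[float, float]:
    """t-test of a fitted slope or intercept against a theoretical constant.

    The statistic is ``t = |b - B| / Sb`` with ``n - 2`` degrees of
    freedom; the theoretical constant carries no sampling variance, so
    its SD term is zero.  Returns (t, two-tailed p).
    """
    if which == "slope":
        b, se = fit.slope, fit.se_slope
    elif which == "intercept":
        b, se = fit.intercept, fit.se_intercept
    else:
        raise ValueError("which must be 'slope' or 'intercept'")
    if se == 0.0:
        return (0.0, 1.0) if b == theoretical else (np.inf, 0.0)
    t = abs(b - theoretical) / se
    p = 2.0 * sps.t.sf(t, df=fit.n - 2)
    return float(t), float(p)


def two_sample_t(a, b, pooled: bool = True) -> tuple[float, float]:
    """Two-sided Student's t-test; pooled variance by default, Welch
    with ``pooled=False``."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                        equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SMLRModel:
    """Stepwise multiple linear regression result."""

    predictors: list
    coefficients: dict  # includes "intercept"
    se: dict
    t_stats: dict
    p_values: dict
    f_ratio: float
    r2: float
    n: int
    r2_eval: float | None = None  # observed-vs-predicted r^2 on evaluation data
    _ols_result: object = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.coefficients["intercept"], dtype=float)
        for p in self.predictors:
            out += self.coefficients[p] * X[p].to_numpy(dtype=float)
        return out


def smlr(
    y: np.ndarray,
    X: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
    max_steps: int = 100,
) -> SMLRModel:
    """Bidirectional stepwise multiple linear regression.

    Forward step: add the candidate with the smallest coefficient
    p-value, if that p-value is <= ``alpha_enter``.  Backward step: drop
    the included predictor with the largest p-value if it exceeds
    ``alpha_remove``.  Iterate to a fixed point.  An intercept-only model
    is a valid outcome when nothing enters.
    """
    y = np.asarray(y, dtype=float)
    offered = list(X.columns)
    if len(y) <= len(offered) + 2:
        raise ValueError("need n > predictors + 2")
    selected: list = []

    def fit(cols):
        design = sm.add_constant(X[cols].to_numpy(dtype=float)) if cols else \
            np.ones((len(y), 1))
        return sm.OLS(y, design).fit()

    sse_floor = 1e-12 * float(np.var(y)) * len(y)  # guards exact fits
    for _ in range(max_steps):
        changed = False
        # forward
        current_sse = float(fit(selected).ssr)
        remaining = [c for c in offered if c not in selected]
        best_p, best_c = None, None
        for c in remaining:
            res = fit(selected + [c])
            if current_sse - float(res.ssr) <= sse_floor:
                continue  # numerically no improvement (e.g. perfect fit)
            p = res.pvalues[-1]
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p <= alpha_enter:
            selected.append(best_c)
            changed = True
        # backward
        while selected:
            res = fit(selected)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break
    res = fit(selected)
    names = ["intercept"] + selected
    coeffs = dict(zip(names, np.atleast_1d(res.params)))
    ses = dict(zip(names, np.atleast_1d(res.bse)))
    tstats = dict(zip(names, np.atleast_1d(res.tvalues)))
    pvals = dict(zip(names, np.atleast_1d(res.pvalues)))
    return SMLRModel(
        predictors=list(selected),
        coefficients={k: float(v) for k, v in coeffs.items()},
        se={k: float(v) for k, v in ses.items()},
        t_stats={k: float(v) for k, v in tstats.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        f_ratio=float(res.fvalue) if selected else float("nan"),
        r2=float(res.rsquared) if selected else 0.0,
        n=int(len(y)),
        _ols_result=res,
    )


def summarize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-column Avg, SD (ddof=1), Minimum, Maximum, CV (%) and N,
    matching the layout of published summary tables."""
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = {}
    for c in columns:
        x = table[c].to_numpy(dtype=float)
        avg = x.mean()
        sd = x.std(ddof=1)
        rows[c] = {
            "Avg": avg,
            "SD": sd,
            "Minimum": x.min(),
            "Maximum": x.max(),
            "CV": 100.0 * sd / avg if avg != 0 else np.nan,
            "N": x.size,
        }
    return pd.DataFrame(rows).T
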