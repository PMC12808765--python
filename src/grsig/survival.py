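"""Survival stratification and analysis.

Patients are stratified by quartiles of a score (top quartile "High",
bottom "Low", rest "Intermediate"), survival is summarized by the
Kaplan-Meier product-limit estimator, group separation is tested by the
log-rank (Mantel-Cox) test, and the score's effect is quantified by a
univariate Cox proportional-hazards fit. KM and log-rank are backed by
lifelines; the Cox partial likelihood is maximized in-house by Newton's
method with Breslow tie handling (so exact patient duplication leaves the
estimate unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import DataError

STRATA = ("Low", "Intermediate", "High")


@dataclass
class StrataAssignment:
    """Per-patient stratum labels plus the quartile cutpoints used."""

    strata: pd.Series  # patient -> {High, Intermediate, Low}
    q1: float
    q3: float

    def counts(self) -> dict[str, int]:
        return self.strata.value_counts().to_dict()


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards estimate."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": [self.beta],
                "se(coef)": [self.se],
                "HR": [self.hr],
                "HR 95% CI low": [self.ci_low],
                "HR 95% CI high": [self.ci_high],
                "p": [self.p],
            },
            index=["covariate"],
        )


def stratify_quartiles(scores: pd.Series, mode: str = "three_way") -> StrataAssignment:
    """Quartile stratification with type-7 (linear interpolation) quantiles.

    Low: score <= Q1; High: score >= Q3; otherwise Intermediate. In
    ``high_low`` mode the Intermediate patients are dropped. If Q1 == Q3
    (degenerate score) everyone is Intermediate and a warning is issued.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 8:
        raise DataError("need at least 8 patients to stratify by quartiles")
    q1, q3 = np.quantile(scores.to_numpy(), [0.25, 0.75])  # type-7 default
    if q1 == q3:
        warnings.warn("degenerate score distribution (Q1 == Q3); "
                      "assigning everyone to Intermediate", stacklevel=2)
        strata = pd.Series("Intermediate", index=scores.index, name="stratum")
    else:
        strata = pd.Series("Intermediate", index=scores.index, name="stratum")
        strata[scores <= q1] = "Low"
        strata[scores >= q3] = "High"
    if mode == "high_low":
        strata = strata[strata != "Intermediate"]
    elif mode != "three_way":
        raise DataError(f"unknown stratification mode {mode!r}")
    return StrataAssignment(strata=strata, q1=float(q1), q3=float(q3))


def km_estimate(time, event) -> pd.DataFrame:
    """Kaplan-Meier curve: event times, survival probability, numbers at risk."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise DataError("empty stratum")
    if (time <= 0).any():
        raise DataError("survival times must be > 0")
    kmf = KaplanMeierFitter().fit(time, event)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(),
            "survival": surv.to_numpy(),
            "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(),
        }
    )


def logrank_test(time, event, strata) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) chi-square statistic and p over >= 2 strata."""
    strata = pd.Series(strata)
    if strata.nunique() < 2:
        raise DataError("log-rank needs at least two nonempty strata")
    res = multivariate_logrank_test(np.asarray(time, float),
                                    strata.to_numpy(),
                                    np.asarray(event, int))
    return float(res.test_statistic), float(res.p_value)


def cox_fit(time, event, covariate, max_iter: int = 50,
            tol: float = 1e-8) -> CoxFit:
    """Univariate Cox PH fit: Newton on the Breslow partial likelihood.

    Returns the log-hazard coefficient, its standard error, the hazard
    ratio with a 95% Wald CI, and the Wald p-value.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0:
        raise DataError("covariate is constant")
    if d.sum() == 0:
        raise DataError("no events observed")

    # sort by descending time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    t, d, x = t[order], d[order], x[order]
    # group tied event times (Breslow: shared denominator per tied group)
    uniq, inv = np.unique(-t, return_inverse=True)

    beta = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        e = np.exp(beta * x)
        s0 = np.cumsum(e)
        s1 = np.cumsum(x * e)
        s2 = np.cumsum(x * x * e)
        # index of the last subject with time >= t_i (ties share a risk set)
        grp_last = np.searchsorted(inv, inv, side="right") - 1
        s0i, s1i, s2i = s0[grp_last], s1[grp_last], s2[grp_last]
        u = float(np.sum(d * (x - s1i / s0i)))
        info = float(np.sum(d * (s2i / s0i - (s1i / s0i) ** 2)))
        if info <= 0:
            raise DataError("Cox information matrix is singular")
        step = u / info
        beta += step
        if not np.isfinite(beta) or abs(beta) > 50:
            raise DataError("Cox fit diverged (possible complete separation)")
        if abs(u) < tol:
            break
    else:
        raise DataError("Cox fit did not converge")

    se = 1.0 / np.sqrt(info)
    z = stats.norm.ppf(0.975)
    return CoxFit(
        beta=float(beta),
        se=float(se),
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(2 * stats.norm.sf(abs(beta) / se)),
        n_iter=n_iter,
    )


def compare_expression_across_strata(expr: pd.Series,
                                     assignment: StrataAssignment) -> dict:
    """Summarize one gene per stratum and rank-sum test High vs Low.

    Returns per-stratum n/mean/median and the two-sided Mann-Whitney p for
    High vs Low (independent samples). A constant gene yields p = 1.
    """
    expr = pd.Series(expr).astype(float)
    strata = assignment.strata
    hi = expr.loc[strata.index[strata == "High"]]
    lo = expr.loc[strata.index[strata == "Low"]]
    if hi.empty or lo.empty:
        raise DataError("High and Low strata must both be nonempty")
    summary = {
        s: {
            "n": int((strata == s).sum()),
            "mean": float(expr.loc[strata.index[strata == s]].mean()),
            "median": float(expr.loc[strata.index[strata == s]].median()),
        }
        for s in strata.unique()
    }
    pooled = np.concatenate([hi.to_numpy(), lo.to_numpy()])
    if np.ptp(pooled) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
    return {"summary": summary, "p_high_vs_low": p}


def plot_km(time, event, strata, ax=None):
    """Overlay KM curves per stratum (optional figure output)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    strata = pd.Series(strata).reset_index(drop=True)
    t = pd.Series(np.asarray(time, float))
    e = pd.Series(np.asarray(event, int))
    for s in sorted(strata.unique()):
        m = (strata == s).to_numpy()
        KaplanMeierFitter().fit(t[m], e[m], label=str(s)).plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    return ax
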