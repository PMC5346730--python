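"""Median-split survival validation: Kaplan-Meier, log-rank, Cox regression.

Candidate genes are validated on the cohort's follow-up data the way a
single-gene biomarker analysis proceeds: patients are split at the median
of the gene's expression (ties to "high"), the two groups' product-limit
survival curves are compared with the two-group log-rank test, and the
hazard ratio of the high group is quantified with a Cox proportional-hazards
fit on the group indicator (Breslow handling of tied event times,
Newton-Raphson from beta = 0).  Reported per gene: HR, 95% Wald CI, the
percent change in hazard 100*(HR-1), Wald p and log-rank p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CoxFit:
    """Single-covariate Cox proportional-hazards fit."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    percent_risk: float
    n: int
    n_events: int
    converged: bool


@dataclass
class LogrankResult:
    chi2: float
    p: float


def median_split(values: pd.Series) -> pd.Series:
    """Boolean "high" indicator: value >= median (even n: mean of central pair).

    Missing values are dropped with a warning; an all-equal input produces a
    degenerate split (everyone high) and a warning.
    """
    clean = values.dropna()
    if len(clean) < len(values):
        logger.warning("median_split: dropped %d missing values", len(values) - len(clean))
    if len(clean) < 2:
        raise ValueError("need at least 2 non-missing values to split")
    med = float(np.median(clean.to_numpy()))
    high = clean >= med
    if high.all() or not high.any():
        logger.warning("degenerate median split: one group is empty (all values equal?)")
    return high.rename("high")


def group_labels(high: pd.Series) -> pd.Series:
    """Map the boolean indicator to the {high, low} labels used in reports."""
    return high.map({True: "high", False: "low"}).rename("group")


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    One row per distinct event time: time, number at risk, events, S(t).
    Censored subjects leave the risk set after their censoring time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows, surv = [], 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        surv *= 1.0 - d / n_at_risk
        rows.append({"time": float(t), "n_at_risk": n_at_risk, "n_events": d,
                     "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(
    time: np.ndarray, event: np.ndarray, high: np.ndarray
) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time accumulate observed minus expected events in
    the high group and the hypergeometric variance; the statistic is
    (sum O - E)^2 / (sum V) against chi-square with 1 df.  Returns NaN when
    no event time carries variance.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    high = np.asarray(high, dtype=bool)
    if not (high.any() and (~high).any()):
        raise ValueError("both groups must be nonempty")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & high).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & high).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        logger.warning("log-rank variance is zero; statistic undefined")
        return LogrankResult(chi2=float("nan"), p=float("nan"))
    chi2 = o_minus_e**2 / var
    return LogrankResult(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


def _partial_likelihood_terms(time, event, x):
    """Per-event-time (d, sum of x over events, risk-set mask) with Breslow ties."""
    terms = []
    for t in np.unique(time[event == 1]):
        events_here = (time == t) & (event == 1)
        terms.append((int(events_here.sum()), float(x[events_here].sum()), time >= t))
    return terms


def breslow_log_likelihood(beta: float, time, event, x) -> float:
    """Breslow-approximation Cox partial log-likelihood (used by test oracles)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for d, s, risk in _partial_likelihood_terms(time, event, x):
        ll += beta * s - d * np.log(np.sum(np.exp(beta * x[risk])))
    return float(ll)


def _score_and_info(beta: float, terms, x):
    score, info = 0.0, 0.0
    for d, s, risk in terms:
        w = np.exp(beta * x[risk])
        wsum = w.sum()
        m1 = float(np.dot(w, x[risk]) / wsum)
        m2 = float(np.dot(w, x[risk] ** 2) / wsum)
        score += s - d * m1
        info += d * (m2 - m1**2)
    return score, info


def cox_score_test(time, event, x) -> LogrankResult:
    """Score test of beta = 0 in the Cox model (equals log-rank without ties)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    score, info = _score_and_info(0.0, _partial_likelihood_terms(time, event, x), x)
    if info <= 0:
        return LogrankResult(chi2=float("nan"), p=float("nan"))
    chi2 = score**2 / info
    return LogrankResult(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


def cox_fit(
    time, event, covariate, tol: float = 1e-8, max_iter: int = 50
) -> CoxFit:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    The covariate is usually the 0/1 high-expression indicator but any
    single numeric covariate works.  Monotone likelihoods (complete
    separation) are detected by divergence of |beta| and flagged via
    ``converged=False``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    terms = _partial_likelihood_terms(time, event, x)
    beta, converged = 0.0, False
    for _ in range(max_iter):
        score, info = _score_and_info(beta, terms, x)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > 15.0:  # monotone likelihood
            break
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        logger.warning("Cox fit did not converge (beta=%.3g); estimate flagged", beta)
    _score, info = _score_and_info(beta, terms, x)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    hr = float(np.exp(beta))
    z = 1.959963984540054  # 97.5% normal quantile
    wald = beta / se if se > 0 and np.isfinite(se) else float("nan")
    with np.errstate(over="ignore"):  # CI bounds may overflow on flagged fits
        ci_low, ci_high = float(np.exp(beta - z * se)), float(np.exp(beta + z * se))
    return CoxFit(
        beta=float(beta),
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(2.0 * stats.norm.sf(abs(wald))),
        percent_risk=100.0 * (hr - 1.0),
        n=int(len(time)),
        n_events=int(event.sum()),
        converged=converged,
    )


def validate_candidates(
    candidates: pd.DataFrame,
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    continuous: bool = False,
) -> pd.DataFrame:
    """Median-split KM / log-rank / Cox validation of each candidate gene.

    ``candidates`` is a ranking table with a ``gene_id`` column (extra
    columns are carried through); ``survival`` has ``time_days`` and
    ``event`` indexed by sample.  With ``continuous=True`` the Cox covariate
    is the expression value itself instead of the group indicator.
    """
    rows = []
    carried = [c for c in ("rank", "module", "module_score", "log2fc") if c in candidates.columns]
    for _, cand in candidates.iterrows():
        gene = cand["gene_id"]
        if gene not in expression.index:
            logger.warning("candidate %s absent from cohort; skipped", gene)
            continue
        values = expression.loc[gene].reindex(survival.index)
        high = median_split(values)
        surv = survival.loc[high.index]
        time = surv["time_days"].to_numpy()
        event = surv["event"].to_numpy()
        lr = logrank_test(time, event, high.to_numpy())
        covariate = values[high.index].to_numpy() if continuous else high.to_numpy(dtype=float)
        fit = cox_fit(time, event, covariate)
        row = {"gene_id": gene}
        row.update({c: cand[c] for c in carried})
        row.update(
            {"hr": fit.hr, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
             "percent_risk": fit.percent_risk, "wald_p": fit.p, "logrank_p": lr.p,
             "logrank_chi2": lr.chi2, "n": fit.n, "n_events": fit.n_events,
             "converged": fit.converged}
        )
        rows.append(row)
    return pd.DataFrame(rows)
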