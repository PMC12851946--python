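"""Survival statistics: Kaplan-Meier, log-rank, Cox, concordance, bootstrap.

Kaplan-Meier, the two-group log-rank test and Harrell's concordance are
implemented directly (they are small and their hand-tabulated oracles are
part of the test contract); Cox proportional hazards fitting is delegated
to lifelines (Efron tie handling, Wald CIs) behind this module's surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class KMCurve:
    times: np.ndarray          # distinct event times
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv(time, event):
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be aligned 1-D arrays")
    if (time <= 0).any() or not np.isfinite(time).all():
        raise ValueError("survival times must be positive and finite")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return time, event


def km_estimate(time, event, confidence: float = 0.95) -> KMCurve:
    """Product-limit estimator with plain Greenwood variance CIs."""
    time, event = _check_surv(time, event)
    if event.sum() == 0:
        warnings.warn("no events: survival curve is flat at 1")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    n = len(time)
    surv, lo, hi, at_risk, d_out = [], [], [], [], []
    s = 1.0
    green = 0.0
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    for t in uniq:
        r = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / r
        if r > d:
            green += d / (r * (r - d))
        var = s * s * green
        half = z * np.sqrt(var)
        surv.append(s)
        lo.append(max(0.0, s - half))
        hi.append(min(1.0, s + half))
        at_risk.append(r)
        d_out.append(d)
    return KMCurve(
        times=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_out),
        ci_lower=np.asarray(lo),
        ci_upper=np.asarray(hi),
    )


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and two-sided p-value."""
    ta, ea = _check_surv(time_a, event_a)
    tb, eb = _check_surv(time_b, event_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group: log-rank p undefined")
        return np.nan, np.nan
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(all_t[all_e == 1]):
        at = all_t >= t
        n_total = int(at.sum())
        n_b = int((at & grp).sum())
        died = (all_t == t) & (all_e == 1)
        d_total = int(died.sum())
        d_b = int((died & grp).sum())
        o_minus_e += d_b - d_total * n_b / n_total
        if n_total > 1:
            var += (
                d_total
                * (n_b / n_total)
                * (1.0 - n_b / n_total)
                * (n_total - d_total)
                / (n_total - 1)
            )
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class CoxResult:
    coef: pd.Series
    hazard_ratio: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    converged: bool


def cox_fit(time, event, covariates: pd.DataFrame, alpha: float = 0.05) -> CoxResult:
    """Cox proportional hazards fit (Efron ties) with Wald HR CIs."""
    time, event = _check_surv(time, event)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if (cov.nunique() <= 1).any():
        raise ValueError("constant covariate(s): " + ", ".join(cov.columns[cov.nunique() <= 1]))
    df = cov.copy()
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter(alpha=alpha)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # separation / non-convergence is surfaced, never silent
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = fitter.summary
    return CoxResult(
        coef=summ["coef"],
        hazard_ratio=summ["exp(coef)"],
        ci_lower=summ[f"exp(coef) lower {100 * (1 - alpha):g}%"],
        ci_upper=summ[f"exp(coef) upper {100 * (1 - alpha):g}%"],
        p=summ["p"],
        converged=True,
    )


def concordance(risk, time, event) -> float:
    """Harrell's C-index; ties in risk score receive 0.5 credit.

    A pair (i, j) is admissible when the earlier time is an event.  Returns
    NaN when no admissible pairs exist.
    """
    risk = np.asarray(risk, dtype=np.float64)
    time, event = _check_surv(time, event)
    if risk.shape != time.shape:
        raise ValueError("risk and survival arrays must be aligned")
    n = len(risk)
    t_i = time[:, None]
    t_j = time[None, :]
    e_i = event[:, None]
    # i is the earlier, observed event of the pair
    admissible = (e_i == 1) & ((t_i < t_j) | ((t_i == t_j) & (event[None, :] == 0)))
    np.fill_diagonal(admissible, False)
    n_pairs = int(admissible.sum())
    if n_pairs == 0:
        return np.nan
    r_i = risk[:, None]
    r_j = risk[None, :]
    credit = np.where(r_i > r_j, 1.0, np.where(r_i == r_j, 0.5, 0.0))
    return float((credit * admissible).sum() / n_pairs)


def group_tests(values, groups, correlations: dict | None = None) -> dict:
    """Non-parametric group comparison + correlation report with BH correction.

    values/groups define the group comparison (Mann-Whitney for 2 groups,
    Kruskal-Wallis for >= 3).  ``correlations`` optionally maps names to
    (x, y) pairs tested with Pearson and Spearman.  All p-values in the
    report form one BH family.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    report: dict = {"groups": [str(g) for g in labels]}
    pvals, keys = [], []
    if len(labels) == 2:
        u, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        report["mannwhitney_u"] = float(u)
        report["mannwhitney_p"] = float(p)
        keys.append("mannwhitney_p")
        pvals.append(p)
    else:
        h, p = stats.kruskal(*samples)
        report["kruskal_h"] = float(h)
        report["kruskal_p"] = float(p)
        keys.append("kruskal_p")
        pvals.append(p)
    for name, (x, y) in (correlations or {}).items():
        pr, pp = stats.pearsonr(x, y)
        sr, sp = stats.spearmanr(x, y)
        report[f"{name}_pearson_r"] = float(pr)
        report[f"{name}_pearson_p"] = float(pp)
        report[f"{name}_spearman_rho"] = float(sr)
        report[f"{name}_spearman_p"] = float(sp)
        keys += [f"{name}_pearson_p", f"{name}_spearman_p"]
        pvals += [pp, sp]
    rejected, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    report["bh_adjusted"] = {k: float(a) for k, a in zip(keys, adjusted)}
    return report


def bootstrap_ci(
    metric_fn,
    data,
    n_boot: int = 1000,
    seed: int = 0,
    confidence: float = 0.95,
    max_redraws: int = 10000,
):
    """Percentile bootstrap CI of ``metric_fn`` over row resamples of ``data``.

    ``data`` is indexable (array or DataFrame); undefined resamples (metric
    raises or returns NaN) are redrawn, counted, and capped.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    n = len(data)
    is_df = isinstance(data, pd.DataFrame)

    def take(idx):
        return data.iloc[idx] if is_df else np.asarray(data)[idx]

    estimate = float(metric_fn(data))
    draws = []
    redraws = 0
    while len(draws) < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            val = float(metric_fn(take(idx)))
        except Exception:
            val = np.nan
        if np.isnan(val):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("metric undefined on too many bootstrap resamples")
            continue
        draws.append(val)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return estimate, (float(lo), float(hi))
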