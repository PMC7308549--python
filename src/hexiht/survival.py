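"""Survival layer: Kaplan–Meier, log-rank, Cox PH, cutpoint scan, selection.

Overall survival (months, right-censored) is modeled against the per-case
indicator table. The workflow mirrors common practice in prognostic
biomarker studies:

* highly correlated indicators (|r| > 0.90) are pruned before multivariable
  modeling to avoid collinearity;
* each continuous indicator is dichotomized at the cutpoint minimizing the
  log-rank p-value, subject to a minimum group fraction — note that this
  scan optimizes significance, so the reported p at the chosen cutoff is
  selection-biased and flagged as such;
* Kaplan–Meier curves and log-rank tests describe the stratified groups;
* multivariable Cox proportional-hazards models (Efron tie handling) report
  hazard ratios with 95% CIs and the model likelihood-ratio statistic;
* with small cohorts, variable subsets are chosen by forward selection
  inside leave-one-out cross-validation, ranking subsets by how often they
  are selected across folds.

Kaplan–Meier, log-rank and Cox fitting are delegated to lifelines; the
scan, pruning and selection procedures are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ConfigError, UndefinedIndicatorError

DEFAULT_MIN_GROUP_FRACTION = 0.10
CORRELATION_THRESHOLD = 0.90


def _validate_times(times: np.ndarray) -> None:
    if (np.asarray(times, dtype=float) <= 0).any():
        raise ConfigError("survival times must be > 0 months")


@dataclass
class KMEstimate:
    """Product-limit estimate: step times, survival probabilities, risk sets."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan–Meier product-limit estimator of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ConfigError("at least one record is required")
    _validate_times(times)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    sf = kmf.survival_function_
    return KMEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        at_risk=table["at_risk"].to_numpy(dtype=float),
    )


def logrank_test(
    groups: Sequence, times: Sequence[float], events: Sequence[int]
) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _validate_times(times)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ConfigError("log-rank test requires >= 2 non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxModel:
    """Fitted Cox PH model: per-covariate effects plus the model LR test."""

    summary: pd.DataFrame  # index covariate; columns coef, hr, hr_lower, hr_upper, p
    lr_statistic: float
    lr_p: float
    log_likelihood: float
    n: int
    n_events: int

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hazard_ratio(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "event",
) -> CoxModel:
    """Cox proportional-hazards fit (Efron handling of tied event times)."""
    covariates = list(covariates)
    if not covariates:
        raise ConfigError("at least one covariate is required")
    data = df[[duration_col, event_col, *covariates]].dropna()
    _validate_times(data[duration_col].to_numpy())
    if int(data[event_col].sum()) < 1:
        raise ConfigError("Cox fit requires at least one observed event")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ConfigError(f"covariate {c!r} is constant; cannot be fitted")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ConfigError(f"Cox fit failed to converge ({covariates}): {err}") from err
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    lrt = cph.log_likelihood_ratio_test()
    return CoxModel(
        summary=summary,
        lr_statistic=float(lrt.test_statistic),
        lr_p=float(lrt.p_value),
        log_likelihood=float(cph.log_likelihood_),
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
    )


def _logrank_2group(
    times: np.ndarray, events: np.ndarray, high: np.ndarray
) -> tuple[float, float]:
    """Two-sample log-rank via the O−E / hypergeometric-variance form.

    Vectorized over event times; used inside the cutpoint scan where one
    test per candidate split is needed.
    """
    event_times = np.unique(times[events == 1])
    # risk sets and event counts at each event time
    n_at_risk = (times[None, :] >= event_times[:, None]).sum(axis=1)
    n1_at_risk = ((times[None, :] >= event_times[:, None]) & high[None, :]).sum(axis=1)
    is_event = (times[None, :] == event_times[:, None]) & (events[None, :] == 1)
    d = is_event.sum(axis=1)
    d1 = (is_event & high[None, :]).sum(axis=1)
    frac = n1_at_risk / n_at_risk
    o_minus_e = float((d1 - d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1 - frac) * (n_at_risk - d) / (n_at_risk - 1)
    var = float(var_terms[n_at_risk > 1].sum())
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class CutoffResult:
    """Best significance-scan cutpoint for one continuous indicator.

    ``p`` minimizes the log-rank p over admissible splits and is therefore
    selection-biased (no multiplicity correction is applied, matching the
    Cutoff Finder convention); ``selection_biased`` flags this explicitly.
    """

    cutoff: float
    n_low: int
    n_high: int
    logrank_p: float
    logrank_statistic: float
    hazard_ratio: float
    n_candidates: int
    selection_biased: bool = True


def optimal_cutoff(
    values: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
) -> CutoffResult:
    """Scan candidate cutpoints and keep the split minimizing log-rank p.

    Candidates are the midpoints of consecutive sorted unique values; a
    split is admissible when both groups hold at least ``min_group_fraction``
    of the cases. The hazard ratio reported is high-vs-low from a univariate
    Cox fit at the winning cutpoint.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    _validate_times(times)
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise UndefinedIndicatorError(
            "no_admissible_split", "indicator has fewer than 2 distinct values"
        )
    n = len(values)
    min_size = int(np.ceil(min_group_fraction * n))
    best: tuple[float, float, float] | None = None  # (p, stat, cutoff)
    n_candidates = 0
    for cut in (uniq[:-1] + uniq[1:]) / 2.0:
        high = values > cut
        n_high = int(high.sum())
        if n_high < min_size or n - n_high < min_size:
            continue
        n_candidates += 1
        stat, p = _logrank_2group(times, events, high)
        if best is None or p < best[0]:
            best = (p, stat, float(cut))
    if best is None:
        raise UndefinedIndicatorError(
            "no_admissible_split",
            f"no split leaves both groups >= {min_size} cases",
        )
    p, stat, cut = best
    high = values > cut
    df = pd.DataFrame({"time_months": times, "event": events, "high": high.astype(float)})
    try:
        hr = cox_fit(df, ["high"]).hazard_ratio("high")
    except ConfigError:
        hr = float("nan")
    return CutoffResult(
        cutoff=cut,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        logrank_p=p,
        logrank_statistic=stat,
        hazard_ratio=hr,
        n_candidates=n_candidates,
    )


def prune_correlated(
    indicators: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    priority: Sequence[str] | None = None,
) -> list[str]:
    """Greedy correlation pruning in priority order.

    Walking the columns in ``priority`` order (default: table order), an
    indicator is dropped when its absolute Pearson correlation with any
    already-retained indicator exceeds ``threshold``.
    """
    cols = list(priority) if priority is not None else list(indicators.columns)
    unknown = [c for c in cols if c not in indicators.columns]
    if unknown:
        raise ConfigError(f"priority names not in table: {unknown}")
    corr = indicators[cols].corr().abs()
    retained: list[str] = []
    for c in cols:
        if all(corr.loc[c, kept] <= threshold or np.isnan(corr.loc[c, kept])
               for kept in retained):
            retained.append(c)
    return retained


def _forward_select(
    df: pd.DataFrame,
    candidates: Sequence[str],
    duration_col: str,
    event_col: str,
    alpha: float,
) -> tuple[str, ...]:
    """Forward selection on Cox partial likelihood, LR-test entry at alpha."""
    selected: list[str] = []
    ll_current: float | None = None
    remaining = list(candidates)
    while remaining:
        best_name, best_p, best_ll = None, None, None
        for name in remaining:
            try:
                model = cox_fit(df, selected + [name], duration_col, event_col)
            except ConfigError:
                continue
            if ll_current is None:
                # LR vs the null model: lifelines' model LR test
                lr, p = model.lr_statistic, model.lr_p
            else:
                lr = 2.0 * (model.log_likelihood - ll_current)
                p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best_p is None or p < best_p:
                best_name, best_p, best_ll = name, p, model.log_likelihood
        if best_name is None or best_p is None or best_p >= alpha:
            break
        selected.append(best_name)
        ll_current = best_ll
        remaining.remove(best_name)
    return tuple(selected)


def loo_subset_frequency(
    df: pd.DataFrame,
    candidates: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Leave-one-out subset-frequency table for forward-selected Cox models.

    For each fold (one case held out) forward selection is run on the rest;
    the returned table tallies how often each subset was chosen, most
    frequent first. Degenerate folds (no events, fit failure) are skipped and
    counted in the ``n_skipped`` attribute of the result (``.attrs``).
    """
    n = len(df)
    if n < 10:
        raise ConfigError("leave-one-out selection needs n >= 10")
    tallies: dict[tuple[str, ...], int] = {}
    n_skipped = 0
    for i in range(n):
        fold = df.drop(df.index[i])
        try:
            subset = _forward_select(fold, candidates, duration_col, event_col, alpha)
        except ConfigError:
            n_skipped += 1
            continue
        tallies[subset] = tallies.get(subset, 0) + 1
    rows = [
        {"subset": subset, "n_folds": count, "frequency": count / (n - n_skipped)}
        for subset, count in sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    out = pd.DataFrame(rows, columns=["subset", "n_folds", "frequency"])
    out.attrs["n_skipped"] = n_skipped
    return out


def stratify_pr_groups(values: Sequence[float]) -> np.ndarray:
    """Three-group stratification of PR percentages: <20 low, 20–80 moderate, >80 high.

    The moderate-expression band is where intratumoral PR heterogeneity
    (entropy) peaks, so the three groups separate the non-linear prognostic
    effect of PR expression.
    """
    arr = np.asarray(values, dtype=float)
    if ((arr < 0) | (arr > 100)).any():
        raise ConfigError("PR percentages must lie in [0, 100]")
    labels = np.where(arr < 20, "low", np.where(arr <= 80, "moderate", "high"))
    return labels


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values, for users who opt into multiplicity correction."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float))
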