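"""Data-driven TSR cut-off derivation and survival analysis.

Two cut-off strategies are provided, mirroring how automated TSR thresholds
are derived in practice:

* ``youden_cutoff`` — binarize survival at a fixed horizon (3-year DFS or
  5-year OS by default), build the ROC over observed TSR scores and pick the
  threshold maximizing the Youden index J = sensitivity + specificity - 1.
* ``logrank_scan_cutoff`` — the Mesker-style discriminative scan: for every
  threshold on a percent grid, split the cohort and compute the two-group
  log-rank statistic; the cut-off is the threshold with maximal chi-square.
  The scan performs many correlated tests, so the result carries a
  multiplicity warning rather than a corrected p value.

Survival machinery (Kaplan-Meier curves, log-rank tests, Cox proportional
hazards with Wald confidence intervals, reversed-KM median follow-up)
delegates to lifelines; chi-square association tests use scipy. Cohorts are
plain pandas DataFrames read from TSV with columns ``id``, ``tsr_percent``,
``dfs_months``, ``dfs_event``, ``os_months``, ``os_event`` plus free
covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "CohortError",
    "CutoffResult",
    "load_cohort",
    "validate_cohort",
    "endpoint_columns",
    "binarize_at_horizon",
    "youden_cutoff",
    "logrank_scan_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "reverse_km_followup",
    "association_test",
    "survival_report",
]

REQUIRED_COLUMNS = ("id", "tsr_percent", "dfs_months", "dfs_event", "os_months", "os_event")

#: Default binarization horizons per endpoint (months): 3-year DFS, 5-year OS.
DEFAULT_HORIZONS = {"dfs": 36.0, "os": 60.0}


class CohortError(ValueError):
    """Raised for malformed cohort tables or degenerate analysis inputs."""


def endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint not in ("dfs", "os"):
        raise CohortError(f"endpoint must be 'dfs' or 'os', got {endpoint!r}")
    return f"{endpoint}_months", f"{endpoint}_event"


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortError(f"cohort table missing columns: {missing}")
    if cohort["id"].duplicated().any():
        dupes = cohort.loc[cohort["id"].duplicated(), "id"].tolist()
        raise CohortError(f"duplicate patient ids: {dupes[:5]}")
    for col in ("dfs_months", "os_months"):
        if (cohort[col] < 0).any():
            raise CohortError(f"negative times in {col}")
    for col in ("dfs_event", "os_event"):
        if not cohort[col].isin([0, 1]).all():
            raise CohortError(f"{col} must be 0/1")
    if ((cohort["tsr_percent"] < 0) | (cohort["tsr_percent"] > 100)).any():
        raise CohortError("tsr_percent outside [0, 100]")
    return cohort


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-separated cohort table."""
    cohort = pd.read_csv(path, sep="\t")
    return validate_cohort(cohort)


@dataclass
class CutoffResult:
    """A derived TSR threshold with its criterion value and scan trace."""

    method: str  # "youden" | "logrank_scan"
    cutoff_percent: float
    criterion_value: float  # Youden J or log-rank chi-square
    scan: list[tuple[float, float]]  # (threshold, criterion) trace
    horizon_months: float | None = None  # youden only
    endpoint: str | None = None
    n_used: int = 0
    n_excluded: int = 0
    multiplicity_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "cutoff_percent": float(self.cutoff_percent),
            "criterion_value": float(self.criterion_value),
            "horizon_months": self.horizon_months,
            "endpoint": self.endpoint,
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "multiplicity_warning": self.multiplicity_warning,
            "scan": [[float(t), float(c)] for t, c in self.scan],
        }


# ---------------------------------------------------------------------------
# ROC / Youden cut-off
# ---------------------------------------------------------------------------


def binarize_at_horizon(
    cohort: pd.DataFrame, endpoint: str, horizon_months: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Turn a survival endpoint into a binary outcome at a fixed horizon.

    Outcome 1 = event on or before the horizon; outcome 0 = event-free with
    follow-up reaching the horizon. Patients censored before the horizon are
    uninformative at that horizon and are excluded; their count is returned.
    """
    if not horizon_months > 0:
        raise CohortError("horizon_months must be positive")
    tcol, ecol = endpoint_columns(endpoint)
    t = cohort[tcol].to_numpy(dtype=float)
    e = cohort[ecol].to_numpy(dtype=int)
    event_by_horizon = (e == 1) & (t <= horizon_months)
    event_free = t >= horizon_months
    keep = event_by_horizon | event_free
    outcomes = event_by_horizon[keep].astype(int)
    scores = cohort["tsr_percent"].to_numpy(dtype=float)[keep]
    n_excluded = int((~keep).sum())
    if (outcomes == 1).sum() < 2 or (outcomes == 0).sum() < 2:
        raise CohortError(
            "fewer than 2 patients in an outcome class after horizon exclusion"
        )
    return scores, outcomes, n_excluded


def youden_cutoff(
    scores,
    outcomes,
    *,
    endpoint: str | None = None,
    horizon_months: float | None = None,
) -> CutoffResult:
    """ROC-optimal threshold by exhaustive Youden-index maximization.

    Candidate thresholds are the unique observed scores; a patient is called
    positive when score > threshold. Ties in J resolve to the smallest
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if scores.shape != outcomes.shape:
        raise CohortError("scores and outcomes must be paired")
    n_pos = int((outcomes == 1).sum())
    n_neg = int((outcomes == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CohortError("both outcome classes must be present")

    thresholds = np.unique(scores)
    # sens(t) = P(score > t | outcome 1); spec(t) = P(score <= t | outcome 0)
    pos_scores = np.sort(scores[outcomes == 1])
    neg_scores = np.sort(scores[outcomes == 0])
    sens = 1.0 - np.searchsorted(pos_scores, thresholds, side="right") / n_pos
    spec = np.searchsorted(neg_scores, thresholds, side="right") / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return CutoffResult(
        method="youden",
        cutoff_percent=float(thresholds[best]),
        criterion_value=float(j[best]),
        scan=list(zip(thresholds.tolist(), j.tolist())),
        horizon_months=horizon_months,
        endpoint=endpoint,
        n_used=int(scores.size),
    )


def youden_cutoff_from_cohort(
    cohort: pd.DataFrame, endpoint: str, horizon_months: float | None = None
) -> CutoffResult:
    """Convenience wrapper: binarize at the horizon, then maximize Youden J."""
    if horizon_months is None:
        horizon_months = DEFAULT_HORIZONS[endpoint]
    scores, outcomes, n_excluded = binarize_at_horizon(cohort, endpoint, horizon_months)
    result = youden_cutoff(scores, outcomes, endpoint=endpoint, horizon_months=horizon_months)
    result.n_excluded = n_excluded
    return result


# ---------------------------------------------------------------------------
# Log-rank discriminative scan
# ---------------------------------------------------------------------------


def logrank_scan_cutoff(
    cohort: pd.DataFrame,
    endpoint: str,
    grid_step: float = 1.0,
    min_group_fraction: float = 0.10,
) -> CutoffResult:
    """Threshold maximizing two-group log-rank discrimination.

    Thresholds run on a percent grid across the observed score range;
    thresholds leaving either group below ``min_group_fraction`` of the
    cohort are discarded for stability. The reported maximum is subject to
    the scan's multiple-testing inflation, flagged on the result.
    """
    tcol, ecol = endpoint_columns(endpoint)
    scores = cohort["tsr_percent"].to_numpy(dtype=float)
    times = cohort[tcol].to_numpy(dtype=float)
    events = cohort[ecol].to_numpy(dtype=int)
    if int(events.sum()) < 20:
        raise CohortError("log-rank scan requires at least 20 patients with events")

    n = scores.size
    lo = np.ceil(scores.min() / grid_step) * grid_step
    hi = np.floor(scores.max() / grid_step) * grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)

    trace: list[tuple[float, float]] = []
    best_t = None
    best_chi2 = -np.inf
    min_n = min_group_fraction * n
    for t in grid:
        high = scores > t
        n_high = int(high.sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        res = _ll_logrank(times[~high], times[high], events[~high], events[high])
        chi2 = float(res.test_statistic)
        trace.append((float(t), chi2))
        if chi2 > best_chi2:
            best_chi2 = chi2
            best_t = float(t)
    if best_t is None:
        raise CohortError("no admissible thresholds under the group-size guard")
    return CutoffResult(
        method="logrank_scan",
        cutoff_percent=best_t,
        criterion_value=best_chi2,
        scan=trace,
        endpoint=endpoint,
        n_used=n,
        multiplicity_warning=True,
    )


# ---------------------------------------------------------------------------
# Survival machinery
# ---------------------------------------------------------------------------


def km_estimate(times, events, horizons: tuple[float, ...] = ()) -> dict:
    """Kaplan-Meier product-limit estimate with optional t-year rates.

    Returns timeline, survival probabilities, numbers at risk, and the
    survival rate at each requested horizon (step-function value).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise CohortError("times and events must be paired")
    if (times < 0).any():
        raise CohortError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    rates = {float(h): float(kmf.predict(h)) for h in horizons}
    return {
        "timeline": timeline,
        "survival": survival,
        "at_risk": at_risk,
        "rates": rates,
        "median": float(kmf.median_survival_time_),
    }


def logrank_test(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank test; each group is a (times, events) pair."""
    ta, ea = (np.asarray(v, dtype=float) for v in group_a)
    tb, eb = (np.asarray(v, dtype=float) for v in group_b)
    if ta.size == 0 or tb.size == 0:
        raise CohortError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise CohortError("no events in pooled data")
    res = _ll_logrank(ta, tb, ea, eb)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(cohort: pd.DataFrame, endpoint: str, terms: list[str]) -> pd.DataFrame:
    """Cox proportional hazards fit; returns one row per term.

    Columns: ``hr``, ``ci_lower``, ``ci_upper`` (95% Wald), ``p``, ``coef``,
    ``se``. Passing one term gives the univariate model; several terms give
    the covariate-adjusted (multivariate) model.
    """
    tcol, ecol = endpoint_columns(endpoint)
    df = cohort[[tcol, ecol, *terms]].dropna()
    if int(df[ecol].sum()) < 1:
        raise CohortError("Cox model requires at least one event")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=tcol, event_col=ecol)
    summary = cph.summary
    return pd.DataFrame(
        {
            "hr": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
            "coef": summary["coef"],
            "se": summary["se(coef)"],
        }
    )


def reverse_km_followup(cohort: pd.DataFrame, endpoint: str = "os") -> float:
    """Median follow-up by reversed Kaplan-Meier (censoring as the event).

    Returns ``inf`` when the median is not reached (open upper bound).
    """
    tcol, ecol = endpoint_columns(endpoint)
    if len(cohort) == 0:
        raise CohortError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort[tcol], 1 - cohort[ecol])
    return float(kmf.median_survival_time_)


def association_test(
    cohort: pd.DataFrame, variable: str, group_label: str | pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square between the TSR grouping and a categorical variable.

    ``group_label`` may be a column name or an aligned label series. Returns
    the (uncorrected) chi-square statistic, the p value, and the contingency
    table.
    """
    labels = cohort[group_label] if isinstance(group_label, str) else group_label
    if cohort[variable].nunique() < 2:
        raise CohortError(f"variable {variable!r} needs >= 2 levels")
    table = pd.crosstab(labels, cohort[variable])
    expected = stats.contingency.expected_freq(table.to_numpy())
    if (expected == 0).any():
        raise CohortError("expected cell count of zero in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), float(p), table


def survival_report(
    cohort: pd.DataFrame,
    endpoint: str,
    cutoff_percent: float,
    covariates: list[str] | None = None,
    horizons: tuple[float, ...] | None = None,
) -> dict:
    """Stratify a cohort at a TSR cut-off and run the standard analyses.

    Produces per-group KM rates, the log-rank comparison, univariate (and,
    with covariates, adjusted) Cox hazard ratios for the stroma-high group,
    and the reversed-KM median follow-up.
    """
    cohort = validate_cohort(cohort)
    if horizons is None:
        horizons = (DEFAULT_HORIZONS[endpoint],)
    tcol, ecol = endpoint_columns(endpoint)
    high = cohort["tsr_percent"] > cutoff_percent
    if high.sum() < 2 or (~high).sum() < 2:
        raise CohortError("fewer than 2 patients in a TSR group at this cut-off")
    low_grp = cohort.loc[~high]
    high_grp = cohort.loc[high]

    km_low = km_estimate(low_grp[tcol], low_grp[ecol], horizons)
    km_high = km_estimate(high_grp[tcol], high_grp[ecol], horizons)
    chi2, p = logrank_test((low_grp[tcol], low_grp[ecol]), (high_grp[tcol], high_grp[ecol]))

    work = cohort.copy()
    work["stroma_high"] = high.astype(int)
    uni = cox_fit(work, endpoint, ["stroma_high"])
    report = {
        "endpoint": endpoint,
        "cutoff_percent": float(cutoff_percent),
        "n_low": int((~high).sum()),
        "n_high": int(high.sum()),
        "km_rates_low": km_low["rates"],
        "km_rates_high": km_high["rates"],
        "logrank_chi2": chi2,
        "logrank_p": p,
        "cox_univariate": {
            "hr": float(uni.loc["stroma_high", "hr"]),
            "ci_lower": float(uni.loc["stroma_high", "ci_lower"]),
            "ci_upper": float(uni.loc["stroma_high", "ci_upper"]),
            "p": float(uni.loc["stroma_high", "p"]),
        },
        "median_followup_months": reverse_km_followup(cohort, endpoint),
    }
    if covariates:
        multi = cox_fit(work, endpoint, ["stroma_high", *covariates])
        report["cox_adjusted"] = {
            term: {
                "hr": float(multi.loc[term, "hr"]),
                "ci_lower": float(multi.loc[term, "ci_lower"]),
                "ci_upper": float(multi.loc[term, "ci_upper"]),
                "p": float(multi.loc[term, "p"]),
            }
            for term in multi.index
        }
    return report
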