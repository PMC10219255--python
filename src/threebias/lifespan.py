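"""Lifespan assay statistics for fully observed (uncensored) cohorts.

Deaths are collected daily, so lifespans are integer days with heavy ties
and every individual has an observed event.  The battery compares two
cohorts three ways, each aimed at a different feature of the survival
distribution:

- **log-rank test** -- the whole survival curve; standard
  observed-minus-expected accumulation over distinct death days with the
  hypergeometric variance handling ties.
- **median Fisher test** -- the median lifespan; two-sided Fisher exact
  test on the 2x2 table of group against (lifespan > pooled median).
- **Wang-Allison test** -- the maximum lifespan; the same construction at
  the pooled 90th-percentile threshold.

Bonferroni adjustment (min(1, m*p)) covers multiple cohort comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy.stats import fisher_exact

from .containers import SurvivalCohort


def km_curve(cohort: SurvivalCohort) -> pd.DataFrame:
    """Empirical survival step function S(t) = fraction alive after day t.

    With no censoring the Kaplan-Meier estimator reduces to the empirical
    survival function.  Returns a DataFrame with columns ``day`` (0 and
    every distinct death day) and ``survival``; S is non-increasing, starts
    at 1 and reaches 0 at the last death.
    """
    days, counts = np.unique(cohort.lifespans, return_counts=True)
    at_risk = cohort.n - np.cumsum(counts)
    surv = at_risk / cohort.n
    return pd.DataFrame(
        {
            "day": np.concatenate(([0], days)),
            "survival": np.concatenate(([1.0], surv)),
        }
    )


def survival_at(cohort: SurvivalCohort, day: float) -> float:
    """Fraction of the cohort with lifespan strictly greater than ``day``."""
    return float(np.mean(cohort.lifespans > day))


def logrank(a: SurvivalCohort, b: SurvivalCohort) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2, p) from the chi2_1 reference.

    Ties (shared death days) are handled with the hypergeometric variance
    at each distinct day.  Symmetric in the two cohorts.
    """
    res = _lifelines_logrank(
        a.lifespans,
        b.lifespans,
        event_observed_A=np.ones(a.n),
        event_observed_B=np.ones(b.n),
    )
    return float(res.test_statistic), float(res.p_value)


def _threshold_table(
    a: SurvivalCohort, b: SurvivalCohort, threshold: float
) -> np.ndarray:
    """2x2 table of group x (lifespan > threshold vs <= threshold)."""
    return np.array(
        [
            [int((a.lifespans > threshold).sum()), int((a.lifespans <= threshold).sum())],
            [int((b.lifespans > threshold).sum()), int((b.lifespans <= threshold).sum())],
        ]
    )


def _fisher_on_threshold(
    a: SurvivalCohort, b: SurvivalCohort, threshold: float
) -> tuple[np.ndarray, float, bool]:
    table = _threshold_table(a, b, threshold)
    degenerate = (table.sum(axis=0) == 0).any()
    if degenerate:
        return table, 1.0, True
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p), False


def median_fisher(
    a: SurvivalCohort, b: SurvivalCohort
) -> dict:
    """Median-lifespan comparison via Fisher's exact test.

    Dichotomizes every individual at the pooled median lifespan m
    (lifespan > m vs <= m) and applies the two-sided Fisher exact test to
    the resulting group x outcome table.  Group medians are reported
    descriptively.  A zero margin (everyone on one side of m) makes the
    table uninformative; p is reported as 1 with ``degenerate=True``.
    """
    pooled = np.concatenate([a.lifespans, b.lifespans])
    m = float(np.median(pooled))
    table, p, degenerate = _fisher_on_threshold(a, b, m)
    return {
        "median_a": a.median,
        "median_b": b.median,
        "pooled_median": m,
        "table": table,
        "p": p,
        "degenerate": degenerate,
    }


def wang_allison(
    a: SurvivalCohort, b: SurvivalCohort, quantile: float = 0.9
) -> dict:
    """Maximum-lifespan comparison (Wang-Allison test).

    Thresholds at the pooled ``quantile`` lifespan (default the 90th
    percentile); ties fall in the "<= threshold" cell.  Two-sided Fisher
    exact p on the group x (above/below) table.  At quantile 0.5 this is
    the median Fisher test.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    pooled = np.concatenate([a.lifespans, b.lifespans])
    threshold = float(np.quantile(pooled, quantile))
    table, p, degenerate = _fisher_on_threshold(a, b, threshold)
    return {
        "threshold": threshold,
        "quantile_a": a.quantile(quantile),
        "quantile_b": b.quantile(quantile),
        "table": table,
        "p": p,
        "degenerate": degenerate,
    }


def adjust_bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for each p.

    ``m`` defaults to the number of p-values and may not be smaller.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def compare_cohorts(
    control: SurvivalCohort,
    treated: SurvivalCohort,
    bonferroni_m: int = 1,
    wa_quantile: float = 0.9,
) -> pd.DataFrame:
    """Full test battery for one treated-vs-control comparison.

    Runs the log-rank, median Fisher and Wang-Allison tests and returns a
    tidy one-row-per-test DataFrame with raw and Bonferroni-adjusted
    p-values (``bonferroni_m`` = number of comparisons in the experiment).
    """
    chi2, p_lr = logrank(control, treated)
    med = median_fisher(control, treated)
    wa = wang_allison(control, treated, wa_quantile)
    if bonferroni_m < 1:
        raise ValueError("bonferroni_m must be >= 1")
    raw = np.array([p_lr, med["p"], wa["p"]])
    # each test is adjusted for the m cohort comparisons in the experiment
    adjusted = np.concatenate([adjust_bonferroni([p], bonferroni_m) for p in raw])
    return pd.DataFrame(
        {
            "test": ["logrank", "median_fisher", "wang_allison"],
            "statistic": [chi2, med["pooled_median"], wa["threshold"]],
            "control_summary": [control.n, med["median_a"], wa["quantile_a"]],
            "treated_summary": [treated.n, med["median_b"], wa["quantile_b"]],
            "p_value": raw,
            "p_bonferroni": adjusted,
        }
    )
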