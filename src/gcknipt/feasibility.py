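"""Feasibility summaries: turnaround times, gestational age at report, and
the study's nonparametric group comparisons."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._exceptions import InvalidInputError
from .qc import Outcome, PregnancyReportOutcome

__all__ = [
    "TurnaroundRecord",
    "GroupComparison",
    "FeasibilitySummary",
    "quantile_summary",
    "turnaround_summary",
    "wilcoxon_rank_sum",
    "spearman_correlation",
]

EARLY_REFERRAL_WEEKS = 20.0
MILESTONE_WEEKS = 28.0


@dataclass(frozen=True)
class TurnaroundRecord:
    pregnancy_id: str
    ga_first_sample: float
    outcome: PregnancyReportOutcome
    ga_at_report: float | None = None
    turnaround_weeks: float | None = None
    n_samples: int = 1
    assay_preexisting: bool = False

    @property
    def reported(self) -> bool:
        return self.outcome.outcome is Outcome.REPORTED


@dataclass(frozen=True)
class GroupComparison:
    """Medians/IQRs of two groups plus the rank-sum comparison."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    summary_a: dict | None
    summary_b: dict | None
    statistic: float | None
    p_value: float | None


@dataclass(frozen=True)
class FeasibilitySummary:
    n_pregnancies: int
    n_reported: int
    outcome_counts: dict
    turnaround: dict
    ga_at_report: dict
    early_referral: dict
    by_n_samples: GroupComparison
    by_assay_preexisting: GroupComparison
    spearman_ga_vs_turnaround: dict


def quantile_summary(values: list[float]) -> dict:
    """Median and IQR by linear-interpolation (type 7) quantiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot summarise an empty list")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    return {"n": int(arr.size), "median": float(q50), "iqr": [float(q25), float(q75)]}


def wilcoxon_rank_sum(a: list[float], b: list[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact p when both groups have n <= 10 and there are no ties; normal
    approximation with tie correction otherwise.  Returns (U statistic for
    group a, p value).
    """
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = list(a) + list(b)
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x: list[float], y: list[float]) -> tuple[float, float]:
    """Spearman's rho (Pearson correlation of mid-ranks) with t-approximation
    p value on n - 2 degrees of freedom.  Constant input yields rho = nan."""
    if len(x) != len(y):
        raise InvalidInputError("x and y must have equal length")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _compare_groups(
    label_a: str, vals_a: list[float], label_b: str, vals_b: list[float]
) -> GroupComparison:
    stat = p = None
    if vals_a and vals_b:
        stat, p = wilcoxon_rank_sum(vals_a, vals_b)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(vals_a),
        n_b=len(vals_b),
        summary_a=quantile_summary(vals_a) if vals_a else None,
        summary_b=quantile_summary(vals_b) if vals_b else None,
        statistic=stat,
        p_value=p,
    )


def turnaround_summary(records: list[TurnaroundRecord]) -> FeasibilitySummary:
    """Summarise reporting feasibility over a cohort.

    Covers: outcome tally; turnaround median/IQR overall and split by
    single-vs-multiple samples and by pre-existing-vs-new assay (rank-sum
    comparisons); gestational age at report overall and for pregnancies
    referred before 20 weeks, with the proportion of those reported before
    28 weeks; and Spearman correlation of referral gestational age with
    turnaround.
    """
    if not records:
        raise InvalidInputError("no records supplied")
    reported = [r for r in records if r.reported and r.turnaround_weeks is not None]
    if not reported:
        raise InvalidInputError("no reported pregnancies to summarise")
    counts: dict[str, int] = {}
    for r in records:
        key = r.outcome.outcome.value
        counts[key] = counts.get(key, 0) + 1

    turnarounds = [float(r.turnaround_weeks) for r in reported]
    gas = [float(r.ga_at_report) for r in reported if r.ga_at_report is not None]

    early = [r for r in reported if r.ga_first_sample < EARLY_REFERRAL_WEEKS]
    early_gas = [float(r.ga_at_report) for r in early if r.ga_at_report is not None]
    early_summary = {
        "n": len(early),
        "ga_at_report": quantile_summary(early_gas) if early_gas else None,
        "prop_reported_before_28wk": (
            sum(g < MILESTONE_WEEKS for g in early_gas) / len(early_gas)
            if early_gas
            else None
        ),
    }

    single = [t for t, r in zip(turnarounds, reported) if r.n_samples == 1]
    multiple = [t for t, r in zip(turnarounds, reported) if r.n_samples > 1]
    pre = [t for t, r in zip(turnarounds, reported) if r.assay_preexisting]
    new = [t for t, r in zip(turnarounds, reported) if not r.assay_preexisting]

    ga_first = [float(r.ga_first_sample) for r in reported]
    if len(reported) >= 3:
        rho, rho_p = spearman_correlation(ga_first, turnarounds)
    else:
        rho, rho_p = float("nan"), float("nan")

    return FeasibilitySummary(
        n_pregnancies=len(records),
        n_reported=len(reported),
        outcome_counts=counts,
        turnaround=quantile_summary(turnarounds),
        ga_at_report=quantile_summary(gas) if gas else {},
        early_referral=early_summary,
        by_n_samples=_compare_groups("single_sample", single, "multiple_samples", multiple),
        by_assay_preexisting=_compare_groups("preexisting_assay", pre, "new_assay", new),
        spearman_ga_vs_turnaround={"rho": rho, "p_value": rho_p},
    )
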