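"""Diagnostic-accuracy statistics for paired binary tests of fetal genotype.

The positive class throughout is N/M (the fetus inherited the maternal
variant).  Sensitivity, specificity, PPV and NPV carry exact binomial
(Clopper-Pearson) confidence intervals; paired tests on the same subjects
are compared with McNemar's test (sensitivity/specificity), the
generalized score statistic of Leisenring, Alonzo & Pepe (PPV/NPV), and a
stratified paired bootstrap on the difference in empirical AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from ._exceptions import (
    InfeasibleParametersError,
    InvalidInputError,
    UndefinedAUCError,
)

__all__ = [
    "TwoByTwo",
    "Proportion",
    "AccuracyMeasures",
    "PairedPredictions",
    "ROCCurve",
    "McNemarResult",
    "ScoreTestResult",
    "BootstrapAUCResult",
    "build_contingency",
    "clopper_pearson",
    "accuracy_measures",
    "mcnemar_compare",
    "generalized_score_compare",
    "roc_curve",
    "bootstrap_auc_compare",
    "youden_optimal_threshold",
    "paired_sample_size",
    "round_half_away",
]

MCNEMAR_EXACT_CUTOFF = 25  # exact binomial branch when b + c < this


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero (the
    convention used for printed integer percentages)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class TwoByTwo:
    """Predicted-vs-confirmed contingency table; "positive" = N/M."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("contingency counts must be non-negative")
        if self.n == 0:
            raise InvalidInputError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def concordant(self) -> int:
        return self.tp + self.tn


@dataclass(frozen=True)
class Proportion:
    """A proportion with its confidence interval; ``defined`` is False when
    the denominator is zero."""

    estimate: float | None
    low: float | None
    high: float | None
    k: int
    n: int
    defined: bool = True

    @property
    def rounded_pct(self) -> int | None:
        return None if self.estimate is None else round_half_away(100.0 * self.estimate)


@dataclass(frozen=True)
class AccuracyMeasures:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion

    def rounded_pct(self) -> dict[str, int | None]:
        return {
            "sensitivity": self.sensitivity.rounded_pct,
            "specificity": self.specificity.rounded_pct,
            "ppv": self.ppv.rounded_pct,
            "npv": self.npv.rounded_pct,
        }


@dataclass(frozen=True)
class PairedPredictions:
    """Per-subject truth and predictions of two tests on the same subjects."""

    truth: tuple[str, ...]
    test_a: tuple[str, ...]
    test_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not len(self.truth) == len(self.test_a) == len(self.test_b):
            raise InvalidInputError("paired prediction lists must have equal length")
        for seq in (self.truth, self.test_a, self.test_b):
            bad = set(seq) - {"NM", "NN"}
            if bad:
                raise InvalidInputError(f"unknown genotype labels: {sorted(bad)}")


@dataclass(frozen=True)
class ROCCurve:
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float
    scores: tuple[float, ...]
    truth: tuple[str, ...]
    auc_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int
    c: int
    method: str  # "exact" or "chi2"
    zero_discordance: bool = False


@dataclass(frozen=True)
class ScoreTestResult:
    statistic: float  # signed z; positive means test B's value is larger
    p_value: float
    value_a: float | None
    value_b: float | None
    defined: bool = True


@dataclass(frozen=True)
class BootstrapAUCResult:
    delta_auc: float
    p_value: float
    auc_a: float
    auc_b: float
    boot_sd: float
    n_boot: int
    low_n_boot_warning: bool = False


def build_contingency(predicted: list[str], confirmed: list[str]) -> TwoByTwo:
    """Cross-tabulate predicted against confirmed genotype (positive = N/M)."""
    if len(predicted) != len(confirmed):
        raise InvalidInputError("predicted and confirmed lists differ in length")
    if not predicted:
        raise InvalidInputError("empty prediction lists")
    bad = (set(predicted) | set(confirmed)) - {"NM", "NN"}
    if bad:
        raise InvalidInputError(f"unknown genotype labels: {sorted(bad)}")
    tp = fp = fn = tn = 0
    for p, c in zip(predicted, confirmed):
        if p == "NM" and c == "NM":
            tp += 1
        elif p == "NM":
            fp += 1
        elif c == "NM":
            fn += 1
        else:
            tn += 1
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not 0.0 < conf < 1.0:
        raise InvalidInputError(f"confidence level must be in (0, 1), got {conf}")
    if n <= 0 or not 0 <= k <= n:
        raise InvalidInputError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - conf
    low = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    high = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(low), float(high)


def _proportion(k: int, n: int, conf: float) -> Proportion:
    if n == 0:
        return Proportion(estimate=None, low=None, high=None, k=k, n=0, defined=False)
    low, high = clopper_pearson(k, n, conf)
    return Proportion(estimate=k / n, low=low, high=high, k=k, n=n)


def accuracy_measures(t: TwoByTwo, conf: float = 0.95) -> AccuracyMeasures:
    """Sensitivity, specificity, PPV and NPV with Clopper-Pearson CIs.

    A measure whose denominator is zero is returned as undefined rather
    than raising.
    """
    return AccuracyMeasures(
        sensitivity=_proportion(t.tp, t.tp + t.fn, conf),
        specificity=_proportion(t.tn, t.tn + t.fp, conf),
        ppv=_proportion(t.tp, t.tp + t.fp, conf),
        npv=_proportion(t.tn, t.tn + t.fn, conf),
    )


def mcnemar_compare(
    p: PairedPredictions,
    stratum: str,
    exact_cutoff: int = MCNEMAR_EXACT_CUTOFF,
) -> McNemarResult:
    """McNemar's test comparing the two tests' correct-call rates within a
    truth stratum.

    ``stratum="diseased"`` restricts to confirmed N/M subjects and
    compares sensitivities; ``"nondiseased"`` restricts to confirmed N/N
    and compares specificities.  Discordant pairs: b = test A correct &
    test B wrong, c = the reverse.  Exact binomial test when b + c <
    ``exact_cutoff``, else the chi-square statistic (b - c)^2 / (b + c)
    without continuity correction.
    """
    if stratum not in ("diseased", "nondiseased"):
        raise InvalidInputError(f"stratum must be 'diseased' or 'nondiseased', got {stratum!r}")
    target = "NM" if stratum == "diseased" else "NN"
    b = c = 0
    for truth, a_pred, b_pred in zip(p.truth, p.test_a, p.test_b):
        if truth != target:
            continue
        a_ok = a_pred == truth
        b_ok = b_pred == truth
        if a_ok and not b_ok:
            b += 1
        elif b_ok and not a_ok:
            c += 1
    if b + c == 0:
        return McNemarResult(
            statistic=0.0, p_value=1.0, b=0, c=0, method="exact", zero_discordance=True
        )
    table = [[0, b], [c, 0]]
    if b + c < exact_cutoff:
        res = _sm_mcnemar(table, exact=True)
        return McNemarResult(
            statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
            b=b, c=c, method="exact",
        )
    res = _sm_mcnemar(table, exact=False, correction=False)
    return McNemarResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), b=b, c=c, method="chi2"
    )


def _gs_one_measure(
    truth: np.ndarray, a_pos: np.ndarray, b_pos: np.ndarray, positive_records: bool
) -> ScoreTestResult:
    """Generalized score test for one predictive value.

    GEE score test (working independence, empirical sandwich variance) of
    the test-identity effect on the outcome among records where the test
    is positive (PPV) or negative (NPV).  Each subject contributes one
    record per test that meets the inclusion rule; subject-level
    clustering enters through the per-subject score contributions.
    """
    if positive_records:
        inc_a, inc_b, outcome = a_pos, b_pos, truth
    else:
        inc_a, inc_b, outcome = ~a_pos, ~b_pos, ~truth
    n_a, n_b = int(inc_a.sum()), int(inc_b.sum())
    value_a = float(outcome[inc_a].mean()) if n_a else None
    value_b = float(outcome[inc_b].mean()) if n_b else None
    if n_a == 0 or n_b == 0:
        return ScoreTestResult(
            statistic=float("nan"), p_value=float("nan"),
            value_a=value_a, value_b=value_b, defined=False,
        )
    n_inc = n_a + n_b
    mu = (outcome[inc_a].sum() + outcome[inc_b].sum()) / n_inc
    zbar = n_b / n_inc
    resid = outcome.astype(float) - mu
    c_i = inc_a * (0.0 - zbar) * resid + inc_b * (1.0 - zbar) * resid
    u = float(c_i.sum())
    v = float((c_i**2).sum())
    if v == 0.0:
        return ScoreTestResult(statistic=0.0, p_value=1.0, value_a=value_a, value_b=value_b)
    z = u / math.sqrt(v)
    return ScoreTestResult(
        statistic=z, p_value=float(2.0 * stats.norm.sf(abs(z))),
        value_a=value_a, value_b=value_b,
    )


def generalized_score_compare(p: PairedPredictions) -> dict[str, ScoreTestResult]:
    """Compare PPV and NPV of two paired binary tests.

    Implements the marginal-regression generalized score statistic for
    predictive values of paired tests; the signed z statistic is positive
    when test B's predictive value exceeds test A's.
    """
    truth = np.array([t == "NM" for t in p.truth])
    a_pos = np.array([t == "NM" for t in p.test_a])
    b_pos = np.array([t == "NM" for t in p.test_b])
    return {
        "ppv": _gs_one_measure(truth, a_pos, b_pos, positive_records=True),
        "npv": _gs_one_measure(truth, a_pos, b_pos, positive_records=False),
    }


def roc_curve(scores: list[float], truth: list[str]) -> ROCCurve:
    """Empirical ROC with AUC equal to the tie-corrected Mann-Whitney
    statistic.  Scores must be oriented so larger means more likely N/M."""
    if len(scores) != len(truth):
        raise InvalidInputError("scores and truth differ in length")
    y = np.array([t == "NM" for t in truth])
    if y.all() or not y.any():
        raise UndefinedAUCError("both classes must be present to form a ROC curve")
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return ROCCurve(
        fpr=tuple(map(float, fpr)),
        tpr=tuple(map(float, tpr)),
        thresholds=tuple(map(float, thr)),
        auc=auc,
        scores=tuple(map(float, s)),
        truth=tuple(truth),
    )


def _strat_indices(truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.flatnonzero(truth), np.flatnonzero(~truth)


def bootstrap_auc_compare(
    scores_a: list[float],
    scores_b: list[float],
    truth: list[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> BootstrapAUCResult:
    """Paired bootstrap comparison of two AUCs on the same subjects.

    Subjects are resampled within the N/M and N/N strata; the same
    resample indexes both score vectors (paired design).  The two-sided p
    value is the normal approximation z = delta / sd(bootstrap deltas).
    """
    y = np.array([t == "NM" for t in truth])
    if y.all() or not y.any():
        raise UndefinedAUCError("both classes must be present")
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if not len(sa) == len(sb) == len(y):
        raise InvalidInputError("paired score vectors must match the truth length")
    auc_a = float(roc_auc_score(y, sa))
    auc_b = float(roc_auc_score(y, sb))
    delta = auc_a - auc_b
    rng = np.random.default_rng(seed)
    pos, neg = _strat_indices(y)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        yi = y[idx]
        deltas[i] = roc_auc_score(yi, sa[idx]) - roc_auc_score(yi, sb[idx])
    sd = float(np.std(deltas, ddof=1))
    if sd == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(delta) / sd))
    return BootstrapAUCResult(
        delta_auc=delta, p_value=p, auc_a=auc_a, auc_b=auc_b,
        boot_sd=sd, n_boot=n_boot, low_n_boot_warning=n_boot < 100,
    )


def youden_optimal_threshold(roc: ROCCurve) -> tuple[float, bool]:
    """Score threshold maximising Youden's J = sensitivity + specificity - 1.

    Returns ``(threshold, degenerate)``.  The threshold is the midpoint
    between the selected cut's score and the next lower distinct score
    (midpoint convention); ties in J break toward higher sensitivity.
    ``degenerate`` is True when J = 0 everywhere (all scores equal), in
    which case the lowest score is returned.
    """
    uniq = np.unique(np.asarray(roc.scores, dtype=float))
    if uniq.size == 1:
        return float(uniq[0]), True
    j = np.asarray(roc.tpr) - np.asarray(roc.fpr)
    if np.allclose(j, 0.0):
        return float(uniq[0]), True
    # candidates ordered by (J, tpr); argmax over lexicographic key
    best = max(range(len(j)), key=lambda i: (j[i], roc.tpr[i]))
    cut = roc.thresholds[best]
    below = uniq[uniq < cut]
    if below.size == 0:
        return float(cut), False
    return float((cut + below[-1]) / 2.0), False


def paired_sample_size(
    delta: float,
    power: float = 0.80,
    alpha: float = 0.05,
    discordance: float | None = None,
) -> int:
    """Sample size for a paired comparison of proportions (McNemar design).

    ``delta`` is the difference in correct-call probability to detect and
    ``discordance`` the total probability that the two tests disagree
    (psi >= delta).  Uses the standard normal-approximation formula

        n = (z_{1-a/2} sqrt(psi) + z_{power} sqrt(psi - delta^2))^2 / delta^2

    rounded up to the smallest integer meeting the target power.
    """
    if not 0.0 < delta < 1.0:
        raise InfeasibleParametersError(f"delta must be in (0, 1), got {delta}")
    if discordance is None:
        discordance = delta
    if discordance < delta or discordance > 1.0:
        raise InfeasibleParametersError(
            f"discordance must lie in [delta, 1], got {discordance}"
        )
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise InfeasibleParametersError("power and alpha must be in (0, 1)")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = (za * math.sqrt(discordance) + zb * math.sqrt(discordance - delta**2)) ** 2 / delta**2
    return int(math.ceil(n))
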