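"""Accuracy measures, paired-test comparisons, ROC/AUC and design size."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gcknipt._exceptions import (
    InfeasibleParametersError,
    InvalidInputError,
    UndefinedAUCError,
)
from gcknipt.accuracy import (
    PairedPredictions,
    TwoByTwo,
    accuracy_measures,
    bootstrap_auc_compare,
    build_contingency,
    clopper_pearson,
    generalized_score_compare,
    mcnemar_compare,
    paired_sample_size,
    roc_curve,
    round_half_away,
    youden_optimal_threshold,
)
from gcknipt.studytables import AC75_TABLE, AC90_TABLE, NIPT_TABLE, paired_labels


class TestBuildContingency:
    @pytest.mark.parametrize("table", [NIPT_TABLE, AC75_TABLE, AC90_TABLE])
    def test_round_trips_published_tables(self, table):
        predicted, confirmed = paired_labels(table)
        assert len(predicted) == 38
        assert build_contingency(predicted, confirmed) == table

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            build_contingency([], [])

    def test_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            build_contingency(["NM"], ["NM", "NN"])
        with pytest.raises(InvalidInputError):
            build_contingency(["XX"], ["NM"])


class TestClopperPearson:
    def test_all_successes_lower_bound(self):
        low, high = clopper_pearson(15, 15)
        assert round(low, 2) == 0.78
        assert high == 1.0

    def test_npv_lower_bound(self):
        low, _ = clopper_pearson(22, 22)
        assert round(low, 2) == 0.85

    def test_zero_successes(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert 0 < high < 1

    def test_invalid_conf_rejected(self):
        with pytest.raises(InvalidInputError):
            clopper_pearson(1, 2, conf=1.5)

    def test_exact_coverage_at_n_20(self):
        """Exhaustive binomial summation: coverage >= 95% for every p."""
        n = 20
        intervals = [clopper_pearson(k, n) for k in range(n + 1)]
        for p in np.linspace(0.001, 0.999, 999):
            pmf = stats.binom.pmf(np.arange(n + 1), n, p)
            cover = sum(
                pmf[k] for k, (lo, hi) in enumerate(intervals) if lo <= p <= hi
            )
            assert cover >= 0.95 - 1e-12


# printed integer percentages: (table, sens, spec, ppv, npv, sens CI, spec CI, ppv CI, npv CI)
PRINTED = [
    (NIPT_TABLE, 100, 96, 94, 100, (78, 100), (78, 100), (70, 100), (85, 100)),
    (AC75_TABLE, 53, 61, 47, 67, (27, 79), (39, 80), (23, 72), (43, 85)),
    (AC90_TABLE, 87, 48, 52, 85, (60, 98), (27, 69), (31, 72), (55, 98)),
]


class TestAccuracyMeasures:
    @pytest.mark.parametrize("table,sens,spec,ppv,npv,s_ci,sp_ci,p_ci,n_ci", PRINTED)
    def test_reproduces_printed_percentages(
        self, table, sens, spec, ppv, npv, s_ci, sp_ci, p_ci, n_ci
    ):
        m = accuracy_measures(table)
        assert m.rounded_pct() == {
            "sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv
        }
        for prop, ci in zip(
            (m.sensitivity, m.specificity, m.ppv, m.npv), (s_ci, sp_ci, p_ci, n_ci)
        ):
            assert (
                round_half_away(100 * prop.low),
                round_half_away(100 * prop.high),
            ) == ci

    def test_perfect_two_subject_table(self):
        m = accuracy_measures(TwoByTwo(1, 0, 0, 1))
        assert all(v == 100 for v in m.rounded_pct().values())

    def test_zero_denominator_flagged_not_raised(self):
        m = accuracy_measures(TwoByTwo(0, 0, 0, 5))
        assert not m.sensitivity.defined
        assert m.sensitivity.estimate is None
        assert m.specificity.defined

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4).filter(lambda t: sum(t) > 0))
    def test_exact_ratio_invariant(self, counts):
        tp, fp, fn, tn = counts
        t = TwoByTwo(tp, fp, fn, tn)
        m = accuracy_measures(t)
        if m.sensitivity.defined:
            assert m.sensitivity.estimate * (tp + fn) == pytest.approx(tp)
        if m.specificity.defined:
            assert m.specificity.estimate * (tn + fp) == pytest.approx(tn)


def _paired_from_discordants(b: int, c: int, stratum_truth: str = "NM"):
    """Build paired predictions whose discordant counts in the given truth
    stratum are exactly (b, c)."""
    truth, ta, tb = [], [], []
    correct = stratum_truth
    wrong = "NN" if stratum_truth == "NM" else "NM"
    for _ in range(b):  # A correct, B wrong
        truth.append(stratum_truth); ta.append(correct); tb.append(wrong)
    for _ in range(c):  # B correct, A wrong
        truth.append(stratum_truth); ta.append(wrong); tb.append(correct)
    return PairedPredictions(tuple(truth), tuple(ta), tuple(tb))


class TestMcNemar:
    def test_balanced_discordance_chi2_branch(self):
        res = mcnemar_compare(_paired_from_discordants(15, 15), "diseased")
        assert res.method == "chi2"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_exact_one_sided_discordance(self):
        res = mcnemar_compare(_paired_from_discordants(5, 0), "diseased")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 * 0.5**5)

    def test_chi2_statistic_closed_form(self):
        res = mcnemar_compare(_paired_from_discordants(20, 5), "diseased")
        assert res.method == "chi2"
        assert res.statistic == pytest.approx((20 - 5) ** 2 / 25)

    def test_zero_discordance_flag(self):
        p = PairedPredictions(("NM",), ("NM",), ("NM",))
        res = mcnemar_compare(p, "diseased")
        assert res.zero_discordance and res.p_value == 1.0

    def test_exact_branch_equals_binomial_enumeration(self):
        """Oracle: two-sided exact p = twice the smaller Binomial(b+c, 1/2)
        tail, capped at 1, by full enumeration."""
        for b in range(0, 12):
            for c in range(0, 12):
                if b + c == 0:
                    continue
                res = mcnemar_compare(_paired_from_discordants(b, c), "diseased")
                n = b + c
                pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
                lo = sum(pmf[: min(b, c) + 1])
                expected = min(1.0, 2 * lo)
                assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_specificity_stratum_uses_nn_truth(self):
        p = PairedPredictions(
            ("NN", "NN", "NM"), ("NN", "NM", "NM"), ("NM", "NN", "NM")
        )
        res = mcnemar_compare(p, "nondiseased")
        assert (res.b, res.c) == (1, 1)


class TestGeneralizedScore:
    def test_identical_tests_give_null(self):
        p = PairedPredictions(
            ("NM", "NN", "NM", "NN"), ("NM", "NN", "NN", "NM"), ("NM", "NN", "NN", "NM")
        )
        res = generalized_score_compare(p)
        assert res["ppv"].statistic == 0.0 and res["ppv"].p_value == 1.0
        assert res["npv"].statistic == 0.0 and res["npv"].p_value == 1.0

    def test_label_swap_symmetry(self):
        truth = ("NM", "NN", "NM", "NN", "NM", "NN")
        ta = ("NM", "NM", "NN", "NN", "NM", "NN")
        tb = ("NM", "NN", "NM", "NM", "NN", "NN")
        r1 = generalized_score_compare(PairedPredictions(truth, ta, tb))
        r2 = generalized_score_compare(PairedPredictions(truth, tb, ta))
        for m in ("ppv", "npv"):
            assert r1[m].p_value == pytest.approx(r2[m].p_value)
            assert r1[m].statistic == pytest.approx(-r2[m].statistic)

    def test_three_subject_toy_against_hand_computed_score(self):
        """Independent oracle: the score components of the marginal
        regression test computed by hand for a 3-subject design."""
        p = PairedPredictions(("NM", "NN", "NM"), ("NM", "NM", "NN"), ("NM", "NN", "NM"))
        # PPV records: A+: s1 (d=1), s2 (d=0); B+: s1 (d=1), s3 (d=1)
        mu = (1 + 0 + 1 + 1) / 4
        zbar = 2 / 4
        c1 = (0 - zbar) * (1 - mu) + (1 - zbar) * (1 - mu)  # s1 in both
        c2 = (0 - zbar) * (0 - mu)  # s2 in A only
        c3 = (1 - zbar) * (1 - mu)  # s3 in B only
        u = c1 + c2 + c3
        v = c1**2 + c2**2 + c3**2
        z_expected = u / math.sqrt(v)
        res = generalized_score_compare(p)["ppv"]
        assert res.statistic == pytest.approx(z_expected)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z_expected)))

    def test_no_positive_predictions_undefined(self):
        p = PairedPredictions(("NM", "NN"), ("NN", "NN"), ("NM", "NN"))
        res = generalized_score_compare(p)
        assert not res["ppv"].defined


def _auc_brute_force(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t == "NM"]
    neg = [s for s, t in zip(scores, truth) if t == "NN"]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p in pos
        for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], ["NM", "NM", "NN", "NN"])
        assert roc.auc == 1.0

    def test_all_ties_give_half(self):
        roc = roc_curve([0.5, 0.5, 0.5, 0.5], ["NM", "NM", "NN", "NN"])
        assert roc.auc == 0.5

    def test_three_point_pair_counting(self):
        roc = roc_curve([0.9, 0.8, 0.3], ["NM", "NN", "NM"])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_curve([0.1, 0.2], ["NM", "NM"])

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.sampled_from(["NM", "NN"])
            ),
            min_size=2,
            max_size=50,
        ).filter(lambda rows: len({t for _, t in rows}) == 2)
    )
    def test_auc_equals_pair_counting_oracle(self, rows):
        scores = [s for s, _ in rows]
        truth = [t for _, t in rows]
        assert roc_curve(scores, truth).auc == pytest.approx(
            _auc_brute_force(scores, truth), abs=1e-12
        )

    def test_monotone_curve(self):
        rng = np.random.default_rng(3)
        scores = list(rng.normal(size=40))
        truth = ["NM" if rng.random() < 0.4 else "NN" for _ in range(40)]
        roc = roc_curve(scores, truth)
        assert all(a <= b for a, b in zip(roc.fpr, roc.fpr[1:]))
        assert all(a <= b for a, b in zip(roc.tpr, roc.tpr[1:]))


class TestBootstrapAUC:
    def test_identical_scores_null(self):
        scores = [0.9, 0.8, 0.3, 0.2, 0.7, 0.1]
        truth = ["NM", "NM", "NN", "NN", "NM", "NN"]
        res = bootstrap_auc_compare(scores, scores, truth, n_boot=200, seed=1)
        assert res.delta_auc == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        truth = ["NM"] * 15 + ["NN"] * 23
        a = list(rng.normal(size=38) + [2.0 if t == "NM" else 0 for t in truth])
        b = list(rng.normal(size=38) + [0.5 if t == "NM" else 0 for t in truth])
        r1 = bootstrap_auc_compare(a, b, truth, n_boot=300, seed=7)
        r2 = bootstrap_auc_compare(a, b, truth, n_boot=300, seed=7)
        assert r1 == r2

    def test_low_n_boot_warning(self):
        truth = ["NM", "NM", "NN", "NN"]
        res = bootstrap_auc_compare([1, 2, 0, 0.5], [2, 1, 0.5, 0], truth, n_boot=50, seed=0)
        assert res.low_n_boot_warning

    def test_detects_auc_gap_at_study_size(self):
        """Scores drawn with true AUCs ~0.99 vs ~0.64 at n = 38 (15/23 class
        split): the paired bootstrap rejects at 5% in most seeded cohorts."""
        rejections = 0
        n_cohorts = 100
        for seed in range(n_cohorts):
            rng = np.random.default_rng(10_000 + seed)
            truth = ["NM"] * 15 + ["NN"] * 23
            shift = np.array([1.0 if t == "NM" else 0.0 for t in truth])
            a = rng.normal(size=38) + 3.29 * shift  # AUC ~ 0.99
            b = rng.normal(size=38) + 0.51 * shift  # AUC ~ 0.64
            res = bootstrap_auc_compare(list(a), list(b), truth, n_boot=300, seed=seed)
            if res.p_value < 0.05:
                rejections += 1
        assert rejections > n_cohorts / 2


class TestYouden:
    def test_perfect_separation_midpoint(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], ["NM", "NM", "NN", "NN"])
        thr, degenerate = youden_optimal_threshold(roc)
        assert not degenerate
        assert thr == pytest.approx(0.5)

    def test_all_equal_scores_flagged(self):
        roc = roc_curve([0.5] * 6, ["NM"] * 3 + ["NN"] * 3)
        thr, degenerate = youden_optimal_threshold(roc)
        assert degenerate and thr == 0.5

    def test_recovers_planted_percentile_cut(self):
        """Equal-variance genotype-conditional percentile model with optimal
        cut at the 91st percentile: the empirical Youden threshold lands
        within +/-2 points (median over seeds, n = 500 per cohort)."""
        mu_nm, mu_nn = 0.84, 1.84  # densities cross at z = 1.34 -> 91st pct
        estimates = []
        for seed in range(11):
            rng = np.random.default_rng(seed)
            truth, pcts = [], []
            for _ in range(500):
                g = "NM" if rng.random() < 0.5 else "NN"
                z = rng.normal(mu_nm if g == "NM" else mu_nn, 1.0)
                truth.append(g)
                pcts.append(100 * stats.norm.cdf(z))
            roc = roc_curve([-p for p in pcts], truth)
            thr, degenerate = youden_optimal_threshold(roc)
            assert not degenerate
            estimates.append(-thr)
        assert abs(float(np.median(estimates)) - 91.0) <= 2.0


class TestPairedSampleSize:
    def test_zero_delta_infeasible(self):
        with pytest.raises(InfeasibleParametersError):
            paired_sample_size(0.0)

    def test_doubling_delta_reduces_n(self):
        n1 = paired_sample_size(0.10, discordance=0.40)
        n2 = paired_sample_size(0.20, discordance=0.40)
        assert n2 < n1

    def test_discordance_below_delta_infeasible(self):
        with pytest.raises(InfeasibleParametersError):
            paired_sample_size(0.3, discordance=0.2)

    def test_formula_matches_simulated_power(self):
        """Simulation oracle: at the returned n the McNemar exact test
        attains the target power (to Monte Carlo error); at half that n it
        does not."""
        delta, psi, power, alpha = 0.23, 0.33, 0.80, 0.05
        n = paired_sample_size(delta, power=power, alpha=alpha, discordance=psi)

        def simulated_power(n_subj: int, reps: int = 4000, seed: int = 17) -> float:
            rng = np.random.default_rng(seed)
            n_disc = rng.binomial(n_subj, psi, size=reps)
            p_b = (psi + delta) / (2 * psi)
            b = rng.binomial(n_disc, p_b)
            c = n_disc - b
            m = np.minimum(b, c)
            with np.errstate(divide="ignore", invalid="ignore"):
                pvals = np.minimum(1.0, 2 * stats.binom.cdf(m, n_disc, 0.5))
            pvals[n_disc == 0] = 1.0
            return float(np.mean(pvals < alpha))

        assert simulated_power(n) >= power - 0.05
        assert simulated_power(max(2, n // 2)) < power
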