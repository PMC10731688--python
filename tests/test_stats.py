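"""Accuracy battery: exact intervals, McNemar branches, subgroup tables."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from screeneval.reference import classify_outcomes, truth_vector
from screeneval.scenarios import run_scenario
from screeneval.stats import (
    MCNEMAR_ASYMPTOTIC,
    MCNEMAR_EXACT,
    StatsError,
    accuracy_report,
    clopper_pearson,
    compare_scenarios,
    confusion,
    detection_crosstab,
    detection_table,
    mcnemar_test,
)

from conftest import make_cohort


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == cm.fn == 0

    def test_printed_tallies(self):
        """2,041 positives with 1,301 detected leaves 740 false negatives."""
        truth = np.zeros(5000, dtype=bool)
        truth[:2041] = True
        d = np.zeros(5000, dtype=bool)
        d[:1301] = True
        cm = confusion(d, truth)
        assert cm.tp == 1301 and cm.fn == 740
        assert round(100 * cm.sensitivity, 1) == 63.7

    def test_manual_count_on_random_fixture(self):
        rng = np.random.default_rng(3)
        d = rng.random(30) < 0.4
        t = rng.random(30) < 0.3
        cm = confusion(d, t)
        cells = [(int(di), int(ti)) for di, ti in zip(d, t)]
        assert cm.tp == cells.count((1, 1))
        assert cm.fp == cells.count((1, 0))
        assert cm.tn == cells.count((0, 0))
        assert cm.fn == cells.count((0, 1))
        assert cm.n == 30

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            confusion([1, 0], [1])


class TestClopperPearson:
    def test_printed_interval(self):
        """1,301/2,041 gives the printed (61.6%, 65.8%) interval."""
        low, high = clopper_pearson(1301, 2041)
        assert round(100 * low, 1) == 61.6
        assert round(100 * high, 1) == 65.8

    def test_boundary_counts(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_tail_inversion_oracle(self):
        """Endpoints invert the binomial tail probabilities to 1e-10: at the
        lower bound P(X >= k) = alpha/2, at the upper P(X <= k) = alpha/2."""
        for k, n in [(5, 10), (1, 100), (99, 100), (137, 562), (1301, 2041)]:
            low, high = clopper_pearson(k, n)
            if 0 < k:
                assert sps.binom.sf(k - 1, n, low) == pytest.approx(0.025, abs=1e-10)
            if k < n:
                assert sps.binom.cdf(k, n, high) == pytest.approx(0.025, abs=1e-10)

    def test_contains_point_estimate(self):
        low, high = clopper_pearson(5, 10)
        assert low < 0.5 < high

    def test_coverage_simulation(self):
        """Exact intervals are conservative: empirical coverage of the 95%
        interval over 2,000 binomial draws (n=500, p=0.7) is >= 0.95."""
        rng = np.random.default_rng(2024)
        ks = rng.binomial(500, 0.7, size=2000)
        covered = 0
        for k in ks:
            low, high = clopper_pearson(int(k), 500)
            covered += low <= 0.7 <= high
        assert covered / 2000 >= 0.95

    def test_invalid_counts(self):
        with pytest.raises(StatsError):
            clopper_pearson(5, 4)


def exact_mcnemar_oracle(b: int, c: int) -> float:
    """Brute-force two-sided exact binomial p: sum of all outcome
    probabilities no larger than the observed one under Bin(b+c, 1/2)."""
    m = b + c
    if m == 0:
        return 1.0
    probs = np.array([comb(m, k, exact=True) for k in range(m + 1)], dtype=float)
    probs /= probs.sum()
    return float(probs[probs <= probs[b] * (1 + 1e-12)].sum())


class TestMcNemar:
    def test_symmetric_discordance(self):
        p, method = mcnemar_test(7, 7)
        assert p == 1.0 and method == MCNEMAR_EXACT

    def test_one_sided_extreme(self):
        """b=0, c=10 gives the exact two-sided tail 2 x 0.5^10."""
        p, method = mcnemar_test(0, 10)
        assert method == MCNEMAR_EXACT
        assert p == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_asymptotic_closed_form(self):
        """b=150, c=100: chi-square statistic (b-c)^2/(b+c) = 10."""
        p, method = mcnemar_test(150, 100)
        assert method == MCNEMAR_ASYMPTOTIC
        assert p == pytest.approx(float(sps.chi2.sf(10.0, 1)), rel=1e-12)

    def test_exact_branch_equals_brute_force_enumeration(self):
        """Exact branch equals binomial enumeration for all b + c <= 15."""
        for m in range(0, 16):
            for b in range(m + 1):
                p, method = mcnemar_test(b, m - b, small_cutoff=25)
                assert method == MCNEMAR_EXACT
                assert p == pytest.approx(exact_mcnemar_oracle(b, m - b), rel=1e-9)

    def test_asymptotic_matches_statsmodels(self):
        for b, c in [(30, 45), (200, 180), (13, 90)]:
            p, _ = mcnemar_test(b, c, small_cutoff=2)
            table = [[0, b], [c, 0]]
            sm = sm_mcnemar(table, exact=False, correction=False)
            assert p == pytest.approx(float(sm.pvalue), rel=1e-9)

    def test_zero_discordance(self):
        assert mcnemar_test(0, 0) == (1.0, MCNEMAR_EXACT)

    def test_negative_counts(self):
        with pytest.raises(StatsError):
            mcnemar_test(-1, 2)


class TestCompareScenarios:
    def test_self_comparison_is_null(self, small_cohort):
        """A scenario against itself: zero deltas, all p = 1."""
        truth = truth_vector(small_cohort)
        res = run_scenario(small_cohort, "combined_reading")
        rep = compare_scenarios(res, res, truth)
        for row in rep.rows:
            assert row.estimate == row.comparator_estimate
            assert row.p_value == 1.0
            assert row.b == row.c == 0

    def test_printed_combined_sensitivity(self):
        """1,509 detected of 2,041 cancers is 73.9%."""
        n = 3000
        truth = np.zeros(n, dtype=bool)
        truth[:2041] = True
        d = np.zeros(n, dtype=bool)
        d[:1509] = True
        cm = confusion(d, truth)
        assert round(100 * cm.sensitivity, 1) == 73.9

    def test_mcnemar_power_for_sensitivity_gap(self):
        """A 5-point sensitivity gap at n_pos = 2,000 is detected by the
        paired McNemar test with power > 0.9 over 200 seeded replicates
        (positively correlated readers, as in practice)."""
        rng = np.random.default_rng(404)
        n_pos = 2000
        rejections = 0
        for _ in range(200):
            # shared difficulty: both scenarios detect a common 63% core,
            # plus scenario-specific extras of 7 and 2 points (70% vs 65%)
            base = rng.random(n_pos) < 0.63
            extra_a = ~base & (rng.random(n_pos) < 0.07 / 0.37)
            extra_b = ~base & (rng.random(n_pos) < 0.02 / 0.37)
            det_a = base | extra_a
            det_b = base | extra_b
            b = int((det_a & ~det_b).sum())
            c = int((~det_a & det_b).sum())
            p, _ = mcnemar_test(b, c)
            rejections += p < 0.05
        assert rejections / 200 > 0.9

    def test_recall_rate_uses_exact_binomial(self, small_cohort):
        truth = truth_vector(small_cohort)
        fr = run_scenario(small_cohort, "first_reader")
        sa = run_scenario(small_cohort, "standalone_ai", threshold=9.0)
        rep = compare_scenarios(sa, fr, truth)
        assert rep["recall_rate"].method == "exact_binomial"
        assert rep["sensitivity"].method in (MCNEMAR_EXACT, MCNEMAR_ASYMPTOTIC)

    def test_ppv_variants(self, small_cohort):
        """The restricted PPV pairing is degenerate (p = 1) under a shared
        reference standard; the recalled-by-either variant is informative."""
        truth = truth_vector(small_cohort)
        fr = run_scenario(small_cohort, "first_reader")
        sa = run_scenario(small_cohort, "standalone_ai", threshold=9.0)
        restricted = compare_scenarios(sa, fr, truth, ppv_variant="restricted")
        assert restricted["ppv"].p_value == 1.0
        either = compare_scenarios(sa, fr, truth, ppv_variant="either")
        assert either["ppv"].b + either["ppv"].c > 0

    def test_report_invariants(self, small_cohort):
        truth = truth_vector(small_cohort)
        rep = accuracy_report(run_scenario(small_cohort, "combined_reading"), truth)
        for row in rep.rows:
            assert row.ci_low <= row.estimate <= row.ci_high
            assert row.estimate == row.k / row.n  # exact integer ratio


@pytest.fixture(scope="module")
def cohort_with_results(small_cohort):
    truth = truth_vector(small_cohort)
    labels = classify_outcomes(small_cohort)
    results = [
        run_scenario(small_cohort, "first_reader"),
        run_scenario(small_cohort, "standalone_ai", threshold=9.0,
                     threshold_mode="ai_sens"),
    ]
    return small_cohort, labels, truth, results


class TestDetectionTable:
    def test_rates_match_groupby_tally(self, cohort_with_results):
        """Rates equal an independent group-by tally of detected cancers."""
        df, labels, truth, results = cohort_with_results
        table = detection_table(results, df, labels)
        fr = results[0].decisions.astype(bool)
        cancer = labels["positive"].to_numpy()
        all_row = table[table["level"] == "all cancers"].iloc[0]
        assert all_row["n_total"] == int(cancer.sum())
        assert all_row["first_reader:detected"] == int((fr & cancer).sum())
        # spot-check one subtype level against a direct scan
        sub = df["subtype"].fillna("unknown").astype(str).to_numpy()
        lob = cancer & (sub == "invasive lobular")
        row = table[(table["variable"] == "subtype")
                    & (table["level"] == "invasive lobular")].iloc[0]
        assert row["n_total"] == int(lob.sum())
        assert row["first_reader:detected"] == int((fr & lob).sum())
        assert row["first_reader:rate"] == pytest.approx(
            (fr & lob).sum() / lob.sum())

    def test_invasive_only_rows_exclude_dcis(self, cohort_with_results):
        df, labels, truth, results = cohort_with_results
        table = detection_table(results, df, labels)
        cancer = labels["positive"].to_numpy()
        invasive = cancer & df["invasive"].fillna(False).to_numpy(dtype=bool)
        grade_totals = table[table["variable"] == "grade"]["n_total"].sum()
        assert grade_totals == int(invasive.sum())

    def test_zero_detection_scenario(self, cohort_with_results):
        df, labels, truth, results = cohort_with_results
        never = run_scenario(df, "standalone_ai", threshold=10.0)
        table = detection_table([results[0], never], df, labels)
        assert (table["standalone_ai:detected"] == 0).all()
        rates = table.loc[table["n_total"] > 0, "standalone_ai:rate"]
        assert (rates == 0).all()

    def test_reference_column_has_no_test(self, cohort_with_results):
        df, labels, truth, results = cohort_with_results
        table = detection_table(results, df, labels)
        assert (table["first_reader:method"] == "ref").all()
        assert table["standalone_ai[ai_sens]:p"].notna().sum() > 0


class TestDetectionCrosstab:
    def test_identical_scenarios_have_empty_off_diagonal(self, small_cohort):
        truth = truth_vector(small_cohort)
        res = run_scenario(small_cohort, "first_reader")
        ct = detection_crosstab(res, res, truth)
        assert ct["a_only"] == ct["b_only"] == 0
        assert ct["both"] + ct["neither"] == int(truth.sum())

    def test_marginals_match_detected_totals(self, small_cohort):
        truth = truth_vector(small_cohort)
        a = run_scenario(small_cohort, "first_reader")
        b = run_scenario(small_cohort, "standalone_ai", threshold=9.0)
        ct = detection_crosstab(a, b, truth)
        det_a = int((a.decisions.astype(bool) & truth).sum())
        det_b = int((b.decisions.astype(bool) & truth).sum())
        assert ct["both"] + ct["a_only"] == det_a
        assert ct["both"] + ct["b_only"] == det_b
        assert sum(ct.values()) == int(truth.sum())
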