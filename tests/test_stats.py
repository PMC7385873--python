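"""Cohort statistics: percentages, summaries, rank tests against oracles."""

import math

import numpy as np
import pytest
import scipy.stats as sps

from iclcentration import (
    CentrationRecord,
    CohortParams,
    InputError,
    compute_distances,
    kappa_correlations,
    percent,
    record_from_geometry,
    sample_cohort,
    spearman,
    summarize,
    wilcoxon_signed_rank,
)
from iclcentration.stats import format_p, summary_markdown

from oracles import pearson_on_average_ranks, wilcoxon_enumeration_p


def simple_record(d_hc, eye_id="e"):
    return compute_distances(CentrationRecord(eye_id, "OD", d_hc, 0.0, 0.0, 0.0))


class TestPercent:
    @pytest.mark.parametrize(
        "count, total, expected",
        [(85, 89, 95.51), (84, 89, 94.38), (50, 89, 56.18), (42, 89, 47.19),
         (43, 89, 48.31), (34, 89, 38.20), (3, 89, 3.37), (1, 89, 1.12), (0, 89, 0.00)],
    )
    def test_cohort_tabulation_values(self, count, total, expected):
        assert percent(count, total) == expected

    def test_half_away_from_zero_rounding(self):
        assert percent(1, 800) == 0.13  # 0.125 rounds up, not to even

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            percent(1, 0)
        with pytest.raises(InputError):
            percent(5, 4)


class TestWilcoxon:
    def test_identical_samples_flagged(self):
        a = np.arange(1.0, 9.0)
        res = wilcoxon_signed_rank(a, a)
        assert res.p_value == 1.0 and res.flag == "all-zero-differences"

    def test_six_positive_differences_exact(self):
        """All-positive differences at n=6: two-sided p = 2/64."""
        b = np.zeros(6)
        a = np.array([1.0, 2, 3, 4, 5, 6])
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(2 / 64)
        assert res.statistic == 0.0  # min(W+, W-)

    @pytest.mark.parametrize("n", range(5, 11))
    def test_exact_p_matches_sign_enumeration(self, n, rng):
        """Exact-path p equals the exhaustive 2^n enumeration, ties included."""
        for trial in range(8):
            d = np.round(rng.normal(0, 1, n), 1)  # rounding creates ties
            d[d == 0] = 0.1
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.p_value == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_exact_agrees_with_scipy_when_tie_free(self, rng):
        a = rng.normal(0.3, 1, 20)
        b = rng.normal(0.0, 1, 20)
        ours = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, zero_method="wilcox", mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_normal_approximation_close_to_scipy(self, rng):
        a = rng.normal(0.2, 1, 60)
        b = rng.normal(0.0, 1, 60)
        ours = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, zero_method="wilcox", mode="approx", correction=True)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_signed_rank([1, 2], [3, 4])


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = np.arange(10.0)
        assert spearman(x, np.exp(x)).r == pytest.approx(1.0)
        assert spearman(x, -(x**3)).r == pytest.approx(-1.0)

    def test_tied_fixture_equals_pearson_on_ranks(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 6.0, 5.0, 7.0])
        res = spearman(a, b)
        r_ref, p_ref = pearson_on_average_ranks(a, b)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(10):
            a = np.round(rng.normal(size=15), 1)
            b = np.round(rng.normal(size=15), 1)
            res = spearman(a, b)
            r_ref, _ = pearson_on_average_ranks(a, b)
            assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = spearman(np.ones(8), np.arange(8.0))
        assert math.isnan(res.r) and res.flag == "zero-variance"


class TestSummarize:
    def test_hand_arithmetic(self):
        s = summarize([simple_record(0.2, "a"), simple_record(0.4, "b")])
        assert s.metrics["d_hc_mm"]["mean"] == pytest.approx(0.30)
        assert s.metrics["d_hc_mm"]["sd"] == pytest.approx(0.1414, abs=1e-4)

    def test_identical_records_have_zero_sd(self):
        s = summarize([simple_record(0.3, str(i)) for i in range(6)])
        assert all(v["sd"] == 0 for v in s.metrics.values())

    def test_quadrant_percentages_recompute_from_counts(self):
        eyes = sample_cohort(CohortParams(n_eyes=89), seed=13)
        s = summarize([record_from_geometry(g) for g in eyes])
        for table in s.quadrants.values():
            counts = [v["count"] for v in table.values()]
            assert sum(counts) == 89
            for v in table.values():
                assert v["percent"] == percent(v["count"], 89)
            assert sum(v["percent"] for v in table.values()) == pytest.approx(100, abs=0.05)

    def test_order_invariance(self):
        eyes = sample_cohort(CohortParams(n_eyes=30), seed=8)
        recs = [record_from_geometry(g) for g in eyes]
        s1, s2 = summarize(recs), summarize(list(reversed(recs)))
        assert s1.quadrants == s2.quadrants
        assert s1.metrics["d_hc_mm"]["mean"] == pytest.approx(
            s2.metrics["d_hc_mm"]["mean"], abs=1e-12
        )

    def test_small_cohort_tests_unavailable(self):
        s = summarize([simple_record(0.1 * i, str(i)) for i in range(1, 5)])
        assert all(t.flag == "unavailable" for t in s.wilcoxon.values())

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            summarize([])
        with pytest.raises(InputError):
            summarize([simple_record(0.1)])

    def test_markdown_report_structure(self):
        eyes = sample_cohort(CohortParams(n_eyes=30), seed=8)
        md = summary_markdown(summarize([record_from_geometry(g) for g in eyes]))
        for section in ("Distances", "hole vs cornea", "hole vs pupil",
                        "pupil vs cornea", "Wilcoxon", "Spearman", "Kappa"):
            assert section in md


class TestKappaCorrelations:
    def test_null_coupling_gives_small_r(self):
        p = CohortParams(n_eyes=200, kappa_rho_hpx=0.0, kappa_rho_hpy=0.0)
        recs = [record_from_geometry(g) for g in sample_cohort(p, seed=31)]
        out = kappa_correlations(recs)
        for res in out.values():
            assert abs(res.r) <= 0.2

    def test_negative_coupling_recovered(self):
        p = CohortParams(n_eyes=200, kappa_rho_hpy=-0.4)
        recs = [record_from_geometry(g) for g in sample_cohort(p, seed=32)]
        res = kappa_correlations(recs)["ky_vs_dhpy"]
        assert -0.6 <= res.r <= -0.2

    def test_missing_kappa_flagged_absent(self):
        recs = [simple_record(0.1 * i, str(i)) for i in range(1, 9)]
        out = kappa_correlations(recs)
        assert all(v.flag == "kappa-absent" for v in out.values())


def test_p_value_formatting():
    assert format_p(0.0004) == "< 0.001"
    assert format_p(0.058) == "0.058"
    assert format_p(float("nan")) == "n/a"
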