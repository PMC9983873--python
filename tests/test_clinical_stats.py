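import numpy as np
import pytest
from scipy import stats

from metscreen import (
    IHCRecord,
    LNCountRecord,
    SurvivalRecord,
    ValidationError,
    bin_ihc,
    dichotomize,
    ihc_bin_table,
    km_estimate,
    ln_ratio_group,
    logrank_test,
    mann_whitney,
    marker_correlation,
)
from metscreen.clinical_stats import IHC_BINS, survival_at
from metscreen.io_model import IHC_GRID


class TestIHC:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, "negative"),
            (0.5, "weak_positive"),
            (1.0, "weak_positive"),
            (1.5, "weak_positive"),
            (2.0, "weak_positive"),
            (2.5, "weak_positive"),
            (3.0, "strong_positive"),
            (3.5, "strong_positive"),
            (4.0, "strong_positive"),
        ],
    )
    def test_bin_boundaries(self, score, expected):
        assert bin_ihc(score) == expected

    def test_grid_is_partitioned(self):
        bins = {s: bin_ihc(s) for s in IHC_GRID}
        assert len(bins) == 9
        assert set(bins.values()) == set(IHC_BINS)

    def test_off_grid_score_rejected(self):
        for bad in (2.3, -0.5, 4.5):
            with pytest.raises(ValidationError):
                bin_ihc(bad)

    def test_bin_table_proportions(self):
        records = [
            IHCRecord("a", "primary", 0.0),
            IHCRecord("b", "primary", 2.0),
            IHCRecord("c", "ln_met", 3.0),
            IHCRecord("d", "ln_met", 3.5),
        ]
        table = ihc_bin_table(records).set_index(["tissue", "bin"])
        assert table.loc[("primary", "negative"), "proportion"] == 0.5
        assert table.loc[("ln_met", "strong_positive"), "count"] == 2


class TestMannWhitney:
    def test_exact_small_sample_enumeration(self):
        u, p = mann_whitney([1, 2], [3, 4], mode="exact")
        assert u == 0
        assert p == pytest.approx(2 / 6)

    def test_identical_tied_groups_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3], mode="asymptotic")
        assert p == pytest.approx(1.0)

    def test_exact_matches_independent_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            _, p = mann_whitney(a, b, mode="exact")
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        _, p1 = mann_whitney(a, b, mode="exact")
        _, p2 = mann_whitney(np.exp(a), np.exp(b), mode="exact")
        assert p1 == pytest.approx(p2)

    def test_exact_and_asymptotic_agree_for_moderate_n(self):
        """For n=10 per arm the normal approximation tracks the exact null
        enumeration (scipy's exact method as independent oracle) to 0.02."""
        rng = np.random.default_rng(21)
        for _ in range(100):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            _, p_asym = mann_whitney(a, b, mode="asymptotic")
            p_exact = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact"
            ).pvalue
            assert abs(p_asym - p_exact) < 0.02

    def test_infeasible_exact_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            mann_whitney([1, 2, 2], [3, 4], mode="exact")

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


def rec(time, event, group="a", pid=None):
    return SurvivalRecord(pid or f"p{time}{event}", time, event, group)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # risk 3 at t=1 (censored, no drop); at t=2 risk 2, one event -> 1/2;
        # at t=3 risk 1, one event -> 0
        records = [rec(1, False), rec(2, True), rec(3, True)]
        curve = km_estimate(records)
        assert survival_at(curve, 1) == pytest.approx(1.0)
        assert survival_at(curve, 2) == pytest.approx(0.5)
        assert survival_at(curve, 3) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([rec(t, False) for t in (1, 2, 3)])
        assert (curve["survival"] == 1.0).all()

    def test_single_event_drops_to_zero(self):
        curve = km_estimate([rec(5, True)])
        assert survival_at(curve, 4.9) == 1.0
        assert survival_at(curve, 5) == 0.0

    def test_order_invariant_and_non_increasing(self):
        rng = np.random.default_rng(2)
        records = [
            rec(float(t), bool(e), pid=f"p{i}")
            for i, (t, e) in enumerate(
                zip(rng.exponential(10, 30), rng.random(30) < 0.7)
            )
        ]
        c1 = km_estimate(records)
        c2 = km_estimate(records[::-1])
        assert np.allclose(c1["survival"], c2["survival"])
        assert (np.diff(c1["survival"]) <= 1e-12).all()
        assert c1["survival"].iloc[0] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([])


class TestLogrank:
    def test_duplicated_arms_give_zero_statistic(self):
        arm = [rec(1, True), rec(2, False), rec(3, True)]
        stat, p = logrank_test(arm, arm)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_six_patient_table(self):
        """Arms with events at 1,3,5 and 2,4,6: summing the per-event-time
        observed-minus-expected and hypergeometric variances by hand gives
        O-E = 0.766667 and V = 1.212222, so chi-square = 0.48488."""
        arm_a = [rec(1, True), rec(3, True), rec(5, True)]
        arm_b = [rec(2, True, "b"), rec(4, True, "b"), rec(6, True, "b")]
        stat, p = logrank_test(arm_a, arm_b)
        assert stat == pytest.approx(0.766667**2 / 1.212222, rel=1e-4)
        assert p == pytest.approx(stats.chi2.sf(stat, 1))

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(8)
        a = [rec(float(t), True, pid=f"a{i}")
             for i, t in enumerate(rng.exponential(5, 20))]
        b = [rec(float(t), True, pid=f"b{i}")
             for i, t in enumerate(rng.exponential(8, 20))]
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError, match="at least one event"):
            logrank_test([rec(1, False)], [rec(2, False)])


class TestLNRatio:
    @pytest.mark.parametrize(
        "positive,examined,expected",
        [
            (5, 12, "high_ratio"),   # 0.417 > 0.30
            (0, 15, "no_ln_met"),
            (3, 10, "low_ratio"),    # exactly 30% stays low
            (4, 10, "high_ratio"),
            (1, 40, "low_ratio"),
        ],
    )
    def test_stratification(self, positive, examined, expected):
        assert ln_ratio_group(LNCountRecord("p", positive, examined)) == expected

    def test_custom_cutoff(self):
        assert ln_ratio_group(LNCountRecord("p", 3, 10), cutoff=0.25) == "high_ratio"


class TestCorrelation:
    def test_identity_and_antisymmetry(self):
        x = [1.0, 2.0, 5.0, 9.0]
        for method in ("spearman", "pearson"):
            r, _ = marker_correlation(x, x, method)
            assert r == pytest.approx(1.0)
            r, _ = marker_correlation(x, [-v for v in x], method)
            assert r == pytest.approx(-1.0)

    def test_rank_invariance_of_spearman(self):
        x = np.linspace(0.1, 3, 20)
        y = x**3
        rs, _ = marker_correlation(x, y, "spearman")
        rp, _ = marker_correlation(x, y, "pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            marker_correlation([1, 1, 1], [1, 2, 3])

    def test_median_split(self):
        assert dichotomize([1, 2, 3, 10]) == ["low", "low", "high", "high"]
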