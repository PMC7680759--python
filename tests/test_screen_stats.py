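import numpy as np
import pytest
from scipy import stats

import hatchscreen as hs
from hatchscreen.exceptions import (
    DegenerateExpectationError,
    DegenerateVarianceError,
    InsufficientSampleError,
)
from hatchscreen.screen_stats import bootstrap_t_test
from hatchscreen.tables import load_screen_table, parse_p_value


class TestAlphaPolicy:
    def test_printed_adjusted_alphas(self):
        assert hs.AlphaPolicy(0.05, 6).adjusted == pytest.approx(0.0083, abs=5e-5)
        assert hs.AlphaPolicy(0.05, 4).adjusted == pytest.approx(0.0125)
        assert hs.AlphaPolicy(0.05, 1).adjusted == 0.05

    def test_invalid(self):
        with pytest.raises(ValueError):
            hs.AlphaPolicy(alpha=0.0)
        with pytest.raises(ValueError):
            hs.AlphaPolicy(n_categories=0)


class TestChooseTest:
    def test_normal_homogeneous_prefers_t(self, rng):
        chosen = []
        for _ in range(200):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 1, 50)
            chosen.append(hs.choose_test(a, b)[0])
        # Each screening test falsely rejects ~5% of the time, so the pure-t
        # rate is ~0.95^3; require a clear majority.
        assert chosen.count("t") / len(chosen) > 0.75
        assert all(c in ("t", "welch-t", "mann-whitney-u", "bootstrap-t") for c in chosen)

    def test_skewed_equal_spread_prefers_rank_test(self, rng):
        chosen = []
        for _ in range(200):
            a = np.exp(rng.normal(0, 1, 40))
            b = np.exp(rng.normal(0, 1, 40))
            chosen.append(hs.choose_test(a, b)[0])
        assert chosen.count("mann-whitney-u") / len(chosen) > 0.5

    def test_diagnostics_carry_screening_pvalues(self, rng):
        name, diag = hs.choose_test(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        assert set(diag) == {"shapiro_p", "levene_p"}
        assert all(0 <= p <= 1 for p in diag["shapiro_p"])

    def test_constant_group_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            hs.choose_test([0.1] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            hs.choose_test([0.1, 0.2], [0.1, 0.2, 0.3])


class TestCompareConditions:
    def test_identical_groups_no_separation(self):
        # Heavy outlier defeats normality; identical groups are perfectly
        # homogeneous, so the rank test runs on tied pooled ranks: p = 1.
        values = [0.10, 0.11, 0.10, 0.12, 0.11, 0.10, 0.13, 0.11, 0.12, 0.90]
        result = hs.compare_conditions(values, values)
        assert result.test_name == "mann-whitney-u"
        assert result.p_value == pytest.approx(1.0)

    def test_extreme_separation(self, rng):
        a = 0.10 + rng.normal(0, 0.001, 8)
        b = 0.20 + rng.normal(0, 0.001, 8)  # 100 sd away
        result = hs.compare_conditions(a, b)
        assert result.p_value < 1e-6

    def test_label_swap_symmetry(self, rng):
        for _ in range(20):
            a = rng.normal(0.12, 0.03, 8)
            b = rng.normal(0.18, 0.05, 8)
            ra = hs.compare_conditions(a, b, seed=1)
            rb = hs.compare_conditions(b, a, seed=1)
            if "bootstrap" in ra.test_name:
                assert ra.p_value == pytest.approx(rb.p_value, abs=0.02)
            else:
                assert ra.p_value == pytest.approx(rb.p_value)

    def test_calibrated_effect_detected(self, rng):
        # 16 wells/condition at the suppression-effect calibration.
        params = hs.default_calibration("nabu-effect")
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a = [hs.simulate_well("ci-control", params, rng).hatch_fraction for _ in range(16)]
            b = [hs.simulate_well("ci-treated", params, rng).hatch_fraction for _ in range(16)]
            rejections += hs.compare_conditions(a, b, seed=rng).p_value < 0.05
        assert rejections / n_sim >= 0.99

    def test_alpha_policy_recorded(self, rng):
        result = hs.compare_conditions(
            rng.normal(0, 1, 8), rng.normal(0, 1, 8), policy=hs.AlphaPolicy(0.05, 6)
        )
        assert result.alpha_used == pytest.approx(0.05 / 6)
        assert result.n_per_group == (8, 8)


class TestBootstrapT:
    def test_null_uniformity(self, rng):
        # Under the null the bootstrap p-value should not be systematically small.
        pvals = [
            bootstrap_t_test(rng.normal(0, 1, 8), rng.normal(0, 3, 8), 500, rng)[1]
            for _ in range(200)
        ]
        assert 0.02 < np.mean(np.array(pvals) < 0.05) < 0.10

    def test_seeded_reproducibility(self):
        a = np.array([0.1, 0.12, 0.14, 0.11, 0.13, 0.12, 0.10, 0.15])
        b = np.array([0.2, 0.25, 0.22, 0.28, 0.21, 0.24, 0.26, 0.23])
        p1 = bootstrap_t_test(a, b, 2000, np.random.default_rng(5))[1]
        p2 = bootstrap_t_test(a, b, 2000, np.random.default_rng(5))[1]
        assert p1 == p2 and p1 < 0.01


class TestChiSquareGof:
    def test_hand_example(self):
        result = hs.chi_square_gof((8, 12), 0.5)
        assert result.statistic == pytest.approx(0.8)  # (8-10)^2/10 + (12-10)^2/10

    def test_exact_expectation_is_zero(self):
        assert hs.chi_square_gof((50, 50), 0.5).statistic == pytest.approx(0.0)

    def test_single_pair_cross_rejects_at_adjusted_alpha(self):
        # 10% of 672 eggs against the control cross's 90% reference.
        policy = hs.AlphaPolicy(0.05, 4)
        result = hs.chi_square_gof((67, 605), 0.90, policy)
        assert result.alpha_used == pytest.approx(0.0125)
        assert result.p_value < 0.001
        assert result.significant

    def test_degenerate_expectation(self):
        with pytest.raises(DegenerateExpectationError):
            hs.chi_square_gof((5, 5), 1.0)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(200):
            hatched = int(rng.integers(0, 500))
            unhatched = int(rng.integers(1, 500))
            rate = float(rng.uniform(0.01, 0.99))
            total = hatched + unhatched
            expected = [total * rate, total * (1 - rate)]
            brute = sum(
                (o - e) ** 2 / e for o, e in zip((hatched, unhatched), expected)
            )
            result = hs.chi_square_gof((hatched, unhatched), rate)
            assert result.statistic == pytest.approx(brute, abs=1e-10)
            assert result.p_value == pytest.approx(stats.chi2.sf(brute, df=1), abs=1e-12)


class TestClassifyHit:
    @pytest.mark.parametrize(
        "p, grade",
        [(0.047, "Borderline"), (0.769, "No"), (0.005, "Yes"), (0.04, "Borderline"), (0.05, "No")],
    )
    def test_printed_examples_and_boundaries(self, p, grade):
        assert hs.classify_hit(p).grade == grade

    def test_accepts_test_result(self, rng):
        result = hs.chi_square_gof((8, 12), 0.5)
        call = hs.classify_hit(result, treatment="x")
        assert call.p_value == result.p_value and call.treatment == "x"

    def test_malformed_thresholds(self):
        with pytest.raises(ValueError):
            hs.grade_p_value(0.01, (0.05, 0.04))

    def test_reproduces_all_printed_grades(self):
        for strain in ("wRi", "wMel"):
            table = load_screen_table(strain)
            for _, row in table.iterrows():
                p = parse_p_value(row["p_value"])
                assert hs.classify_hit(p).grade == row["hit_call"], row["treatment"]
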