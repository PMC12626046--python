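"""Precision/agreement statistics: CV, test-retest, LOP, Bland-Altman,
resampling, and rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsdcs import (
    bland_altman,
    cv_series,
    group_compare,
    lop_precision,
    read_session,
    resample_to_device,
    simulate_session,
    test_retest,
)
from nirsdcs.stats import LOPProtocol, spearman


class TestCV:
    # five fixed vectors with spreadsheet-style hand-computed CVs
    HAND_CASES = [
        ([5.0, 5.0, 5.0, 5.0], 0.0),
        ([2.0, 4.0], 100.0 * np.sqrt(2.0) / 3.0),  # 47.1405%
        ([1.0, 2.0, 3.0], 100.0 * 1.0 / 2.0),
        ([10.0, 12.0, 14.0, 16.0], 100.0 * np.sqrt(20.0 / 3.0) / 13.0),
        ([0.5, 1.5, 2.5, 3.5, 4.5], 100.0 * np.sqrt(2.5) / 2.5),
    ]

    @pytest.mark.parametrize("x,expected", HAND_CASES)
    def test_hand_arithmetic(self, x, expected):
        r = cv_series(x)
        assert r.cv_pct == pytest.approx(expected, abs=1e-12)

    def test_two_four_explicit(self):
        r = cv_series([2.0, 4.0])
        assert r.mean == 3.0
        assert r.sd == pytest.approx(np.sqrt(2.0))
        assert r.cv_pct == pytest.approx(47.14045208, abs=1e-6)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        x = np.array([3.0, 4.0, 5.5, 7.0])
        assert cv_series(k * x).cv_pct == pytest.approx(cv_series(x).cv_pct, rel=1e-9)

    def test_zero_mean_flagged_undefined(self):
        r = cv_series([-1.0, 1.0])
        assert r.cv_pct is None and not r.defined

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cv_series([1.0])


class TestTestRetest:
    def test_identical_blocks_zero_inter_cv(self):
        blocks = [np.array([70.0, 71.0, 69.0])] * 5
        r = test_retest(blocks)
        assert r.inter_cv_pct == pytest.approx(0.0, abs=1e-10)

    def test_block_means_hand_oracle(self):
        """Means 70, 71, 70.5, 69.5, 70: sd = sqrt(0.325), CV = 0.81209%."""
        blocks = [np.full(3, m) for m in (70.0, 71.0, 70.5, 69.5, 70.0)]
        r = test_retest(blocks)
        assert r.inter_cv_pct == pytest.approx(100.0 * np.sqrt(0.325) / 70.2, abs=1e-9)
        assert r.inter_cv_pct == pytest.approx(0.8120908, abs=1e-6)

    def test_simulated_repositioning_recovers_generating_cv(self, tmp_path):
        """The repositioning generator is tuned to inter CV ~1.2% (StO2) and
        ~12.6% (BFI); recovered CVs sit near those targets."""
        inter_sto2, inter_bfi = [], []
        for seed in range(6):
            simulate_session("test_retest", tmp_path / f"s{seed}", seed=seed)
            _, ch = read_session(tmp_path / f"s{seed}")
            table = ch["retest"]
            r_s = test_retest([g["sto2"].to_numpy() for _, g in table.groupby("block")])
            r_b = test_retest([g["bfi"].to_numpy() for _, g in table.groupby("block")])
            inter_sto2.append(r_s.inter_cv_pct)
            inter_bfi.append(r_b.inter_cv_pct)
        assert 0.4 < np.mean(inter_sto2) < 2.5
        assert 4.0 < np.mean(inter_bfi) < 25.0

    def test_short_block_rejected(self):
        with pytest.raises(ValueError):
            test_retest([np.array([70.0]), np.array([70.0, 71.0])])


class TestSpearman:
    def test_exact_matches_rank_formula_on_eight_points(self):
        """rho from the brute-force rank formula 1 - 6 sum(d^2)/(n(n^2-1))."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5, 9.0, 3.0])
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        rho_hand = 1 - 6 * np.sum((rx - ry) ** 2.0) / (8 * 63)
        rho, p = spearman(x, y)
        assert rho == pytest.approx(rho_hand, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_perfect_monotone(self):
        rho, p = spearman(np.arange(8.0), np.arange(8.0) ** 2)
        assert rho == pytest.approx(1.0)
        assert p < 0.01


class TestLOPPrecision:
    def test_constant_steps_zero_cv(self):
        t = np.arange(0.0, 180.0)
        trace = pd.DataFrame({"t_s": t, "sto2": 70.0, "bfi": 1e-8})
        steps = pd.DataFrame(
            {"t_s": [0.0, 60.0], "phase": ["inflation", "deflation"], "lop_fraction": [0.4, 0.4]}
        )
        report = lop_precision(trace, steps)
        assert all(s.sto2_cv_pct == pytest.approx(0.0, abs=1e-10) for s in report.steps)

    def test_count_rate_dependent_noise_yields_negative_correlation(self, tmp_path):
        """Noise inversely scaled with count rate across steps drives the
        CV(BFI) vs count-rate rank correlation negative."""
        simulate_session("lop", tmp_path / "s", seed=4)
        _, ch = read_session(tmp_path / "s")
        report = lop_precision(ch["lop_trace"], ch["lop_steps"])
        rho, _ = report.correlations["cv_bfi_vs_count_rate"]
        assert rho < 0

    def test_missing_step_rejected(self):
        trace = pd.DataFrame({"t_s": np.arange(0.0, 30.0), "sto2": 70.0, "bfi": 1e-8})
        steps = pd.DataFrame({"t_s": [60.0], "phase": ["inflation"], "lop_fraction": [0.4]})
        with pytest.raises(ValueError, match="no samples"):
            lop_precision(trace, steps)

    def test_eval_window_longer_than_step_rejected(self):
        with pytest.raises(ValueError):
            LOPProtocol(step_s=10.0, eval_window_s=15.0)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.linspace(60.0, 80.0, 20)
        r = bland_altman(x, x)
        assert r.bias == 0.0 and r.slope == pytest.approx(0.0, abs=1e-12)
        assert r.loa_low == pytest.approx(0.0) and r.loa_high == pytest.approx(0.0)

    def test_constant_offset(self):
        x = np.linspace(60.0, 80.0, 20)
        r = bland_altman(x + 2.0, x)
        assert r.bias == pytest.approx(2.0, abs=1e-12)
        assert r.slope == pytest.approx(0.0, abs=1e-12)

    def test_proportional_bias_detected(self):
        """b = 1.1 a over a wide range: positive slope with p < 0.05 at n=50."""
        rng = np.random.default_rng(6)
        a = np.linspace(40.0, 90.0, 50) + rng.normal(0, 0.5, 50)
        r = bland_altman(1.1 * a, a)
        assert r.slope > 0
        assert r.slope_p < 0.05

    def test_bias_is_mean_difference_and_limits_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(70, 3, 40)
        b = rng.normal(70, 3, 40)
        r = bland_altman(a, b)
        assert r.bias == pytest.approx(np.mean(a - b), rel=1e-12)
        assert r.loa_high - r.bias == pytest.approx(r.bias - r.loa_low, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.arange(5.0), np.arange(6.0))


class TestResample:
    def test_identity_on_identical_grids(self):
        t = np.arange(10.0)
        x = np.sin(t)
        np.testing.assert_array_equal(resample_to_device(t, x, t), x)

    def test_decimation_to_five_second_grid(self):
        t = np.arange(60.0)
        x = t * 2.0
        target = np.arange(0.0, 60.0, 5.0)
        np.testing.assert_array_equal(resample_to_device(t, x, target), x[::5])

    def test_ramp_within_one_source_interval(self):
        t = np.arange(0.0, 100.0)
        x = 0.5 * t
        target = np.array([10.3, 47.8, 99.0])
        held = resample_to_device(t, x, target)
        assert np.all(np.abs(held - 0.5 * target) <= 0.5)  # one source interval

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError):
            resample_to_device(np.arange(10.0), np.arange(10.0), np.array([11.0]))


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        assert not group_compare(x, x).significant

    def test_shifted_groups_detected(self):
        """2 sd shift at n=20 per group is detected."""
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(2.0, 1.0, 20)
        assert group_compare(a, b).significant

    def test_paired_wilcoxon(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 20)
        r = group_compare(a, a + 1.0 + rng.normal(0, 0.1, 20), paired=True)
        assert r.test == "wilcoxon" and r.significant

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            group_compare(np.arange(4.0), np.arange(5.0), paired=True)

    @given(st.sampled_from(["exp", "cube", "affine"]))
    @settings(max_examples=9, deadline=None, derandomize=True)
    def test_invariance_under_monotone_transforms(self, transform):
        """Rank tests are unchanged by strictly monotone transforms of both
        groups."""
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.8, 1.0, 15)
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3.0 * v + 1.0}[transform]
        r0 = group_compare(a, b)
        r1 = group_compare(f(a), f(b))
        assert r1.statistic == pytest.approx(r0.statistic)
        assert r1.p_value == pytest.approx(r0.p_value)

    def test_cohort_direction_icu_vs_healthy(self):
        """Generators drawing around impaired vs healthy medians: lower ReO2
        and AUC detected in the impaired-like group."""
        rng = np.random.default_rng(10)
        healthy_reo2 = rng.normal(1.1, 0.3, 25)
        icu_reo2 = rng.normal(0.8, 0.3, 25)
        healthy_auc = rng.normal(7.7, 2.0, 25)
        icu_auc = rng.normal(3.8, 2.0, 25)
        assert group_compare(icu_reo2, healthy_reo2).significant
        assert group_compare(icu_auc, healthy_auc).significant
        assert np.median(icu_reo2) < np.median(healthy_reo2)
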