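"""Observer threshold summaries and the exact Wilcoxon signed-rank test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lcphantom.calibration import CalibrationModel, LinearFit
from lcphantom.observer import (
    ObserverReading,
    readings_from_csv,
    readings_to_frame,
    simulate_observer_readings,
    summarize,
    thresholds_to_cnr_sc,
    wilcoxon_exact,
)


def brute_force_p(a, b):
    """Direct enumeration oracle: P(min rank-sum <= observed) over all signs."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for m in range(2**n):
        signs = np.array([(m >> i) & 1 for i in range(n)]) * 2 - 1
        w = min(ranks[signs > 0].sum(), ranks[signs < 0].sum())
        if w <= w_obs + 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_all_zero_differences(self):
        res = wilcoxon_exact([1.0, 1.0, 1.2], [1.0, 1.0, 1.2])
        assert res.p_value == 1.0
        assert res.n_effective == 0

    def test_four_same_sign_distinct(self):
        res = wilcoxon_exact([2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert res.p_value == pytest.approx(2 / 16)
        assert res.n_effective == 4

    def test_three_same_sign_distinct(self):
        res = wilcoxon_exact([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.p_value == pytest.approx(2 / 8)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            res = wilcoxon_exact(a, np.zeros(n))
            ref = stats.wilcoxon(a, np.zeros(n), mode="exact", alternative="two-sided")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-4, max_value=4), min_size=1, max_size=9)
    )
    def test_matches_brute_force_with_ties_and_zeros(self, diffs):
        a = np.asarray(diffs, dtype=float)
        b = np.zeros(len(diffs))
        res = wilcoxon_exact(a, b)
        assert res.p_value == pytest.approx(brute_force_p(a, b), abs=1e-12)

    def test_p_is_multiple_of_two_to_minus_n_when_tie_free(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            d = rng.permutation(np.arange(1, n + 1)) * rng.choice([-1, 1], n)
            res = wilcoxon_exact(d.astype(float), np.zeros(n))
            scaled = res.p_value * 2**res.n_effective
            assert scaled == pytest.approx(round(scaled), abs=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([1.0, 2.0], [1.0])


class TestSummarize:
    def test_identical_readings(self):
        s = summarize([1.0] * 5)
        assert s.mean_depth == 1.0
        assert s.sd_depth == 0.0
        assert s.ci95 == (1.0, 1.0)

    def test_hand_arithmetic(self):
        s = summarize([1.0, 1.0, 1.2, 1.2, 1.4])
        assert s.mean_depth == pytest.approx(1.16)
        assert s.sd_depth == pytest.approx(0.16733, abs=1e-4)
        assert s.ci95[0] < s.mean_depth < s.ci95[1]

    def test_ci_widens_with_sd(self):
        narrow = summarize([1.0, 1.1, 1.0, 1.1, 1.05])
        wide = summarize([0.6, 1.5, 0.8, 1.4, 1.0])
        assert (wide.ci95[1] - wide.ci95[0]) > (narrow.ci95[1] - narrow.ci95[0])

    def test_permutation_invariance(self):
        vals = [0.8, 1.2, 1.0, 1.4, 0.9]
        a, b = summarize(vals), summarize(vals[::-1])
        assert a == b

    def test_single_reading_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestThresholdConversion:
    model = CalibrationModel(
        "Q1", LinearFit(1.787, -0.086, 0.986), LinearFit(0.686, -0.048, 0.943)
    )
    fit = LinearFit(1.040, -0.003, 0.966)

    def test_zero_sd_propagates_to_zero(self):
        s = summarize([1.12] * 5)
        conv = thresholds_to_cnr_sc(s, self.fit, self.model)
        assert conv.cnr_sd == 0.0
        assert conv.sc_sd == 0.0
        assert conv.cnr_mean == pytest.approx(1.1618, abs=1e-4)
        assert 2.0 < conv.sc_mean < 4.0

    def test_affine_maps_preserve_group_ordering(self):
        lo = thresholds_to_cnr_sc(summarize([0.8] * 5), self.fit, self.model)
        hi = thresholds_to_cnr_sc(summarize([1.6] * 5), self.fit, self.model)
        assert hi.cnr_mean > lo.cnr_mean
        assert hi.sc_mean > lo.sc_mean

    def test_sd_scales_by_chain_slope(self):
        s = summarize([1.0, 1.0, 1.2, 1.2, 1.4])
        conv = thresholds_to_cnr_sc(s, self.fit, self.model)
        assert conv.cnr_sd == pytest.approx(1.040 * s.sd_depth, rel=1e-12)
        assert conv.sc_sd == pytest.approx((1.787 / 0.686) * conv.cnr_sd, rel=1e-12)


class TestSimulatedObservers:
    def test_readings_snap_to_depth_series(self):
        series = [0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4]
        readings = simulate_observer_readings(
            "plate_a", series, LinearFit(1.0, 0.0, 1.0), beam="Q1", seed=5
        )
        assert len(readings) == 5
        assert all(r.limiting_depth in series for r in readings)

    def test_deterministic_given_seed(self):
        series = [0.5, 1.0, 1.5]
        f = LinearFit(1.0, 0.0, 1.0)
        a = simulate_observer_readings("p", series, f, beam="Q1", seed=3)
        b = simulate_observer_readings("p", series, f, beam="Q1", seed=3)
        assert [r.limiting_depth for r in a] == [r.limiting_depth for r in b]

    def test_csv_roundtrip_with_series_validation(self, tmp_path):
        readings = [
            ObserverReading("obs1", "A", "Q1", "plate_a", 1.0),
            ObserverReading("obs2", "A", "Q1", "plate_a", 1.2),
        ]
        path = tmp_path / "readings.csv"
        readings_to_frame(readings).to_csv(path, index=False)
        back = readings_from_csv(path, depth_series=[1.0, 1.2, 1.4])
        assert [r.limiting_depth for r in back] == [1.0, 1.2]
        with pytest.raises(ValueError, match="depth series"):
            readings_from_csv(path, depth_series=[0.5, 0.7])
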