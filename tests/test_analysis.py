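"""Cycle segmentation, CCI, strategy classification, stability, statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import balancesim as bs
from balancesim.analysis import (NON_SIGNIFICANT, StrategyTimeline,
                                 UndefinedCorrelation,
                                 ankle_dominance_fraction, cci_curve,
                                 cci_series, classify_strategy,
                                 cop_com_stability, paired_tests, pearson,
                                 segment_cycles, strategy_summary,
                                 strategy_timeline)
from balancesim.datasets import (reference_cci_integrals,
                                 reference_dominant_strategy)


class TestSegmentCycles:
    def test_ten_seconds_gives_eight_cycles(self):
        fs = 1000.0
        series = np.sin(2 * np.pi * np.arange(10001) / fs)
        ens = segment_cycles(series, fs, frequency=1.0, discard=2.0)
        assert ens.n_cycles == 8
        assert ens.cycles.shape == (8, 1000)

    def test_pure_sinusoid_has_zero_ensemble_sd(self):
        fs = 500.0
        t = np.arange(0, 10, 1 / fs)
        series = np.sin(2 * np.pi * 1.0 * t)
        ens = segment_cycles(series, fs)
        assert np.allclose(ens.sd(), 0.0, atol=1e-9)

    def test_constant_series(self):
        ens = segment_cycles(np.full(5000, 3.3), 500.0)
        assert np.allclose(ens.mean(), 3.3)
        assert np.allclose(ens.sd(), 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment_cycles(np.zeros(1500), 1000.0, discard=2.0)


class TestCCI:
    def test_equal_moderate_activation(self):
        cci = cci_curve(np.full(10, 0.5), np.full(10, 0.5))
        assert np.allclose(cci, 1.0)

    def test_silent_agonist_gives_zero(self):
        cci = cci_curve(np.zeros(10), np.full(10, 0.8))
        assert np.allclose(cci, 0.0)

    def test_full_co_contraction_is_two(self):
        cci = cci_curve(np.ones(5), np.ones(5))
        assert np.allclose(cci, 2.0)

    def test_integral_of_constant_curve(self):
        s = cci_series(np.full(1001, 0.5), np.full(1001, 0.5), 1000.0)
        assert s.integral == pytest.approx(1.0)  # CCI = 1 over one second

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=30))
    def test_bounds_symmetry_identity(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        cci = cci_curve(a, b)
        assert np.all(cci >= 0.0) and np.all(cci <= 2.0)
        assert np.allclose(cci, cci_curve(b, a))          # symmetric
        assert np.allclose(cci_curve(a, a), 2 * a)        # CCI(a, a) = 2a

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cci_curve(np.array([1.2]), np.array([0.5]))


class TestPearson:
    def test_perfect_linear(self):
        a = np.arange(10.0)
        assert pearson(a, 2 * a + 1) == pytest.approx(1.0)

    def test_anti_phase(self):
        a = np.arange(10.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        mu_a, mu_b = a.mean(), b.mean()
        sa, sb = a.std(ddof=1), b.std(ddof=1)
        direct = np.sum((a - mu_a) / sa * (b - mu_b) / sb) / (len(a) - 1)
        assert pearson(a, b) == pytest.approx(direct, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 1000))
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        assert pearson(scale * a + shift, b) == \
            pytest.approx(pearson(a, b), abs=1e-9)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelation):
            pearson(np.ones(5), np.arange(5.0))


class TestClassifyStrategy:
    TRUTH = [(+0.8, +0.6, "ankle"), (+0.8, -0.6, "knee"),
             (-0.5, +0.5, "hip"), (-0.5, -0.5, "mixed")]

    @pytest.mark.parametrize("r_hk,r_ak,expected", TRUTH)
    def test_sign_table(self, r_hk, r_ak, expected):
        assert classify_strategy(r_hk, r_ak) == expected

    def test_exhaustive_sixteen_cases(self):
        """All sign/dead-band combinations of the two coefficients."""
        levels = {+0.9: "pos", +0.03: "dead", -0.03: "dead", -0.9: "neg"}
        table = {("pos", "pos"): "ankle", ("pos", "neg"): "knee",
                 ("neg", "pos"): "hip", ("neg", "neg"): "mixed"}
        for r1, k1 in levels.items():
            for r2, k2 in levels.items():
                expected = NON_SIGNIFICANT if "dead" in (k1, k2) \
                    else table[(k1, k2)]
                assert classify_strategy(r1, r2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_strategy(1.5, 0.0)


class TestStrategyTimeline:
    def _ens(self, mat):
        from balancesim.analysis import CycleEnsemble
        return CycleEnsemble("", np.asarray(mat, dtype=float), 100.0)

    def test_common_signal_gives_all_ankle(self):
        rng = np.random.default_rng(0)
        common = rng.normal(size=(8, 20))
        tl = strategy_timeline(self._ens(common), self._ens(common * 2),
                               self._ens(common + 0.0))
        assert all(lab == "ankle" for lab in tl.labels)

    def test_sign_construction_gives_all_hip(self):
        rng = np.random.default_rng(1)
        knee = rng.normal(size=(8, 15))
        tl = strategy_timeline(self._ens(-knee), self._ens(knee),
                               self._ens(knee))
        assert all(lab == "hip" for lab in tl.labels)

    def test_constant_moments_non_significant(self):
        const = np.ones((8, 10))
        tl = strategy_timeline(self._ens(const), self._ens(const),
                               self._ens(const))
        assert all(lab == NON_SIGNIFICANT for lab in tl.labels)

    def test_correlation_taken_across_cycles(self):
        # hip correlates with knee only at sample 0; elsewhere anti
        rng = np.random.default_rng(2)
        knee = rng.normal(size=(8, 3))
        hip = -knee.copy()
        hip[:, 0] = knee[:, 0]
        tl = strategy_timeline(self._ens(hip), self._ens(knee),
                               self._ens(knee))
        assert tl.labels[0] == "ankle"
        assert tl.labels[1] == tl.labels[2] == "hip"


class TestStrategySummary:
    def _tl(self, labels):
        n = len(labels)
        return StrategyTimeline(np.zeros(n), np.zeros(n), list(labels))

    def test_dominant_is_mode(self):
        tl = self._tl(["ankle"] * 6 + ["knee"] * 4)
        assert tl.dominant() == frozenset({"ankle"})

    def test_exact_tie_reported_as_set(self):
        tl = self._tl(["ankle"] * 5 + ["hip"] * 5)
        assert tl.dominant() == frozenset({"ankle", "hip"})

    def test_percentages_partition(self):
        tls = {(100.0, 0.0): self._tl(["ankle"] * 3 + ["knee"] * 2),
               (100.0, 2.0): self._tl(["hip"] * 4 + ["mixed"]),
               (150.0, 0.0): self._tl(["ankle", "knee", "hip", "mixed"])}
        dom, overall = strategy_summary(tls)
        for _, row in overall.iterrows():
            assert row.sum() == pytest.approx(100.0)
        assert dom.loc[100.0, 0.0] == "ankle"
        assert dom.loc[100.0, 2.0] == "hip"

    def test_tie_formatting(self):
        tls = {(100.0, 0.0): self._tl(["ankle", "hip"])}
        dom, _ = strategy_summary(tls)
        assert dom.loc[100.0, 0.0] == "ankle/hip"


class TestAnkleDominance:
    def test_reference_table_scores_94_percent(self):
        dom = reference_dominant_strategy()
        assert ankle_dominance_fraction(dom, 20.0) == 94.0

    def test_all_ankle_table(self):
        dom = pd.DataFrame([["Ankle"] * 3], index=[100],
                           columns=[0.0, 2.0, 4.0])
        assert ankle_dominance_fraction(dom, 20.0) == 100.0

    def test_no_ankle_table(self):
        dom = pd.DataFrame([["Knee", "Hip", "Mixed"]], index=[100],
                           columns=[0.0, 2.0, 4.0])
        assert ankle_dominance_fraction(dom, 20.0) == 0.0

    def test_ties_count_as_containing_ankle(self):
        dom = pd.DataFrame([["Ankle/Hip", "Knee"]], index=[100],
                           columns=[0.0, 2.0])
        assert ankle_dominance_fraction(dom, 20.0) == 50.0

    def test_reference_cci_table_shape(self):
        cci = reference_cci_integrals()
        assert cci.shape == (15, 10)
        assert set(cci.index.get_level_values(0)) == {100, 150, 200}


class TestStability:
    def test_cop_equals_com_is_zero(self):
        s = cop_com_stability(np.full(100, 0.05), np.full(100, 0.05))
        assert np.allclose(s.series, 0.0) and s.mean == 0.0

    def test_constant_offset(self):
        com = np.linspace(0, 0.1, 50)
        s = cop_com_stability(com + 0.03, com)
        assert s.mean == pytest.approx(0.03)

    def test_random_series_mean_oracle(self):
        rng = np.random.default_rng(7)
        cop = rng.normal(size=500)
        com = rng.normal(size=500)
        s = cop_com_stability(cop, com)
        assert s.mean == pytest.approx(float(np.mean(cop - com)), abs=1e-12)

    def test_flight_samples_excluded_and_counted(self):
        cop = np.array([0.1, np.nan, 0.3, np.nan])
        com = np.array([0.0, 0.0, 0.1, 0.0])
        s = cop_com_stability(cop, com)
        assert s.n_flight_excluded == 2
        assert s.mean == pytest.approx(0.15)


class TestPairedTests:
    def test_symmetric_differences_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        res = paired_tests(a, b)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_textbook_five_pairs_match_formula(self):
        a = np.array([12.0, 15.0, 9.0, 13.0, 11.0])
        b = np.array([10.0, 13.0, 10.0, 11.0, 10.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        res = paired_tests(a, b, comparison="100vs150", metric="mean act")
        assert res.t == pytest.approx(t_hand, abs=1e-9)
        assert res.n == 5
        from scipy import stats
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert res.p == pytest.approx(p_hand, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_tests(np.array([1.0]), np.array([2.0]))

    def test_degenerate_zero_variance(self):
        with pytest.raises(UndefinedCorrelation):
            paired_tests(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_stats_report_table(self):
        from balancesim.analysis import stats_report
        rng = np.random.default_rng(3)
        mags = 10
        vals = {"mean activation": {100.0: rng.uniform(0, 1, mags),
                                    150.0: rng.uniform(0, 1, mags),
                                    200.0: rng.uniform(0, 1, mags)},
                "cci area": {100.0: np.arange(10.0),
                             150.0: np.arange(10.0) + 1.0,  # constant shift
                             200.0: rng.uniform(0, 5, mags)}}
        df = stats_report(vals)
        assert len(df) == 4  # 2 metrics x 2 comparisons vs baseline
        assert set(df["comparison"]) == {"100 vs 150 ms", "100 vs 200 ms"}
        # the constant-shift comparison is degenerate: zero-variance diffs
        row = df[(df.metric == "cci area")
                 & (df.comparison == "100 vs 150 ms")].iloc[0]
        assert np.isnan(row["t"]) and not row["significant"]
        assert ((df["p"].dropna() >= 0) & (df["p"].dropna() <= 1)).all()
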