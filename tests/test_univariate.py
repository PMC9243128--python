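import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoblock.datamodel import GlycanPeakMatrix, SampleMetadata, default_peak_panel
from glycoblock.datasets import T2DM_TABLE1_PVALUES, t2dm_demographics
from glycoblock.errors import ComputationError, ValidationError
from glycoblock.univariate import (bh_adjust, chi_square_independence, ks_normality,
                                   mann_whitney_u, screen_features, students_t)

from oracles import bh_stepup, mannwhitney_exact_p, students_t_formula


class TestChiSquare:
    @pytest.mark.parametrize("factor,expected", [
        ("education", 9.838), ("age_group", 8.57), ("bmi", 1.302),
    ])
    def test_cohort_demographics_reproduce_published_statistics(self, factor, expected):
        table = t2dm_demographics()[factor]
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(expected, abs=5e-3)
        assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)

    def test_invariant_to_row_and_column_swaps(self, rng):
        table = rng.integers(1, 50, size=(4, 3))
        base = chi_square_independence(table).statistic
        assert chi_square_independence(table[::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(table[:, ::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(table.T).statistic == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_independence([[0, 0], [5, 3]])


class TestStudentsT:
    def test_identical_groups(self):
        res = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_degenerate_zero_variance(self):
        res = students_t([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p) == (0.0, 1.0)
        with pytest.raises(ComputationError):
            students_t([0.0, 0.0], [1.0, 1.0])

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(1.0, 1.0, 30)
        res = students_t(x, y)
        t_expected, df_expected = students_t_formula(x, y)
        assert res.statistic == pytest.approx(t_expected, abs=1e-10)
        assert res.df == df_expected


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic == 0.0  # min-U convention

    def test_identical_multisets_give_half_product(self):
        res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(0.5, 1.0, size=4)
        res = mann_whitney_u(x, y)
        assert res.p == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 5), st.integers(2, 5))
    def test_exact_p_equals_enumeration_property(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = mann_whitney_u(x, y)
        assert res.p == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-12)


class TestBhAdjust:
    def test_published_family_worked_examples(self):
        """In the cohort's 17-test demographic family, education's raw
        p=0.043 at ascending rank 9 adjusts to 0.0812 and physical
        activity's 0.021 at rank 8 adjusts to 0.0446."""
        ps = np.array(list(T2DM_TABLE1_PVALUES.values()))
        names = list(T2DM_TABLE1_PVALUES)
        assert len(ps) == 17
        order = np.argsort(ps)
        ranks = {names[i]: r + 1 for r, i in enumerate(order)}
        assert ranks["education"] == 9
        assert ranks["physical_activity"] == 8
        q = bh_adjust(ps)
        qmap = dict(zip(names, q))
        assert qmap["education"] == pytest.approx(0.0812, abs=5e-5)
        assert qmap["physical_activity"] == pytest.approx(0.0446, abs=5e-5)
        # further published q-values implied by the same family
        assert qmap["age_mean"] == pytest.approx(0.1102, abs=5e-5)
        assert qmap["age_group"] == pytest.approx(0.1128, abs=5e-5)
        assert qmap["bmi"] == pytest.approx(0.8262, abs=5e-5)
        assert qmap["ldl"] == pytest.approx(0.3322, abs=5e-5)

    def test_single_p_and_bounds(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_stepup_definition_and_monotonicity(self, ps):
        ps = np.asarray(ps)
        q = bh_adjust(ps)
        np.testing.assert_allclose(q, bh_stepup(ps), atol=1e-12)
        assert (q >= ps - 1e-15).all() and (q <= 1.0 + 1e-15).all()
        perm = np.random.default_rng(0).permutation(ps.size)
        np.testing.assert_allclose(bh_adjust(ps[perm]), q[perm], atol=1e-12)


class TestKsNormality:
    def test_hand_computed_statistic(self):
        from statistics import NormalDist
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        res = ks_normality(x)
        mu, sd = x.mean(), x.std(ddof=1)
        cdf = np.array([NormalDist(mu, sd).cdf(v) for v in np.sort(x)])
        n = x.size
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert res.statistic == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_detects_exponential_not_normal(self):
        normal_ok = expo_rejected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            normal_ok += ks_normality(rng.normal(size=200)).p > 0.05
            expo_rejected += ks_normality(rng.exponential(size=200)).p < 0.01
        assert normal_ok >= 18
        assert expo_rejected >= 18

    def test_constant_rejected(self):
        with pytest.raises(ComputationError):
            ks_normality(np.ones(10))


class TestScreenFeatures:
    def _cohort(self, effect, seed):
        from glycoblock.simulate import SimulationConfig, simulate_glycome
        cfg = SimulationConfig(n_control=100, n_case=100, effect_size=effect,
                               batch_shift=0.0, batch_scale=1.0, seed=seed)
        return cfg, *simulate_glycome(cfg)

    def test_planted_peaks_reach_q_significance(self):
        from glycoblock.simulate import planted_truth
        hits = 0
        for seed in range(20):
            cfg, X, meta = self._cohort(0.8, seed)
            results, _ = screen_features(X, meta)
            sig = {r.feature_id for r in results if r.q < 0.05}
            hits += planted_truth(cfg) <= sig
        assert hits >= 18

    def test_null_raw_rejection_rate_near_alpha(self):
        ks = Ks = 0
        for seed in range(10):
            _, X, meta = self._cohort(0.0, 50 + seed)
            _, summaries = screen_features(X, meta, alpha=0.05)
            ks += sum(s.k for s in summaries)
            Ks += sum(s.K for s in summaries)
        assert 0.01 < ks / Ks < 0.10  # 390 tests, binomial band around 0.05

    def test_cluster_counts_follow_assignment(self):
        _, X, meta = self._cohort(0.0, 3)
        clusters = {pid: ("A" if i < 20 else "B") for i, pid in enumerate(X.peak_ids)}
        _, summaries = screen_features(X, meta, clusters=clusters)
        by_id = {s.cluster_id: s for s in summaries}
        assert by_id["A"].K == 20 and by_id["B"].K == 19
        assert all(0 <= s.k <= s.K for s in summaries)

    def test_unknown_cluster_feature_rejected(self):
        _, X, meta = self._cohort(0.0, 3)
        with pytest.raises(ValidationError):
            screen_features(X, meta, clusters={"GP99": "A"})
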