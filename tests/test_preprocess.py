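import numpy as np
import pandas as pd
import pytest
from statistics import NormalDist

from glycoblock.datamodel import GlycanPeakMatrix, SampleMetadata, default_peak_panel
from glycoblock.errors import ComputationError, ValidationError
from glycoblock.preprocess import (combat_correct, median_quotient_normalize,
                                   pca_batch_check, rank_transform)
from glycoblock.simulate import SimulationConfig, simulate_glycome


def _matrix(values, prefix="S"):
    values = np.asarray(values, float)
    n, p = values.shape
    return GlycanPeakMatrix(values, tuple(f"{prefix}{i}" for i in range(n)),
                            default_peak_panel(p), compositional=False)


def _meta(batches, groups=None):
    n = len(batches)
    groups = groups if groups is not None else ["control"] * (n // 2) + ["case"] * (n - n // 2)
    return SampleMetadata(pd.DataFrame({"group": groups, "batch": batches},
                                       index=[f"S{i}" for i in range(n)]))


def _batch_shifted(rng, n_per=50, p=10, delta=1.0):
    """Two batches, log-scale shift delta on batch 2, no group effect."""
    base = rng.normal(0.0, 1.0, size=(2 * n_per, p))
    base[n_per:] += delta
    X = _matrix(base)
    batches = ["b1"] * n_per + ["b2"] * n_per
    groups = (["control", "case"] * n_per)[:2 * n_per]
    return X, _meta(batches, groups)


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        X = _matrix(rng.normal(size=(10, 5)))
        meta = _meta(["b1"] * 10)
        out, model = combat_correct(X, meta)
        np.testing.assert_allclose(out.values, X.values, atol=1e-8)
        np.testing.assert_allclose(model.gamma_star, 0.0)
        np.testing.assert_allclose(model.delta2_star, 1.0)
        assert out.compositional is False

    def test_removes_planted_batch_shift(self, rng):
        """A unit shift (1 SD) on every feature is reduced to a small
        between-batch residual; shrinkage leaves at most about half the
        sampling noise of a batch mean, so the residual shrinks with n."""
        X, meta = _batch_shifted(rng, n_per=300, p=15, delta=1.0)
        out, _ = combat_correct(X, meta)
        b = meta.batches_for(X.sample_ids)
        diff = np.abs(out.values[b == "b1"].mean(axis=0)
                      - out.values[b == "b2"].mean(axis=0))
        assert diff.mean() < 0.05

    def test_large_batches_agree_with_no_shrinkage_oracle(self, rng):
        """With heterogeneous true batch effects and n=500 per batch the EB
        estimates approach the raw per-batch location/scale estimates."""
        n_per, p = 2000, 8
        base = rng.normal(0.0, 1.0, size=(2 * n_per, p))
        # real between-feature spread in both location and scale, so the
        # moment-matched priors are diffuse and shrinkage is asymptotically nil
        per_feature_shift = np.linspace(0.5, 3.0, p)
        per_feature_scale = np.linspace(0.8, 1.6, p)
        base[n_per:] = base[n_per:] * per_feature_scale + per_feature_shift
        X = _matrix(base)
        meta = _meta(["b1"] * n_per + ["b2"] * n_per,
                     (["control", "case"] * n_per)[:2 * n_per])
        _, model = combat_correct(X, meta, preserve_group=False)
        np.testing.assert_allclose(model.gamma_star, model.gamma_hat,
                                   rtol=0.02, atol=0.005)
        np.testing.assert_allclose(model.delta2_star / model.delta2_hat, 1.0, rtol=0.02)

    def test_repeated_application_contracts(self, rng):
        """Empirical-Bayes correction leaves a shrunken residual, so a second
        pass changes the data far less than the first and the remaining
        between-batch difference keeps decreasing."""
        X, meta = _batch_shifted(rng, n_per=40, p=6)
        once, _ = combat_correct(X, meta)
        twice, _ = combat_correct(once, meta)
        first_change = np.abs(once.values - X.values).max()
        second_change = np.abs(twice.values - once.values).max()
        assert second_change < 0.5 * first_change
        assert second_change < 0.1

    def test_small_batch_and_zero_variance_errors(self, rng):
        X = _matrix(rng.normal(size=(5, 3)))
        with pytest.raises(ValidationError, match="lonely"):
            combat_correct(X, _meta(["b1"] * 4 + ["lonely"]))
        vals = rng.normal(size=(6, 3))
        vals[:, 1] = 2.5
        with pytest.raises(ComputationError, match="GP2"):
            combat_correct(_matrix(vals), _meta(["b1", "b1", "b1", "b2", "b2", "b2"]))

    def test_preserves_group_effect(self, rng):
        """A true group difference survives correction when groups are
        balanced across batches and preserved in the mean model."""
        n_per = 40
        base = rng.normal(0.0, 1.0, size=(2 * n_per, 6))
        groups = np.array((["control", "case"] * n_per)[:2 * n_per])
        base[groups == "case"] += 0.8
        batches = ["b1"] * n_per + ["b2"] * n_per
        base[np.array(batches) == "b2"] += 1.5
        X = _matrix(base)
        meta = _meta(batches, groups.tolist())
        out, _ = combat_correct(X, meta, preserve_group=True)
        diff = out.values[groups == "case"].mean(axis=0) - \
            out.values[groups == "control"].mean(axis=0)
        assert diff.mean() == pytest.approx(0.8, abs=0.15)


class TestMedianQuotient:
    def test_identical_samples_factors_one(self):
        X = _matrix(np.tile([2.0, 3.0, 5.0], (4, 1)))
        out, factors = median_quotient_normalize(X)
        np.testing.assert_allclose(factors, 1.0)
        np.testing.assert_allclose(out.values, X.values)

    def test_recovers_planted_dilution(self, rng):
        base = rng.uniform(1.0, 5.0, size=7)
        data = np.tile(base, (9, 1))
        data[3] = base * 3.0
        out, factors = median_quotient_normalize(_matrix(data))
        assert factors[3] == pytest.approx(3.0, rel=1e-9)
        np.testing.assert_allclose(out.values[3], base, rtol=1e-9)
        np.testing.assert_allclose(np.delete(factors, 3), 1.0, rtol=1e-12)

    def test_explicit_reference_sample(self):
        X = _matrix([[1.0, 2.0, 4.0]])
        out, factors = median_quotient_normalize(X, reference="S0")
        np.testing.assert_allclose(factors, [1.0])
        np.testing.assert_allclose(out.values, X.values)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError, match="GP2"):
            median_quotient_normalize(_matrix([[1.0, 0.0], [1.0, 2.0]]))

    def test_median_quotient_vs_reference_is_one_after(self, rng):
        data = rng.lognormal(0.0, 0.5, size=(20, 11))
        X = _matrix(data)
        ref = np.median(data, axis=0)
        out, _ = median_quotient_normalize(X)
        q = np.median(out.values / ref[None, :], axis=1)
        np.testing.assert_allclose(q, 1.0, rtol=1e-12)


class TestRankTransform:
    def test_average_rank_examples(self):
        X = _matrix(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        out = rank_transform(X, mode="average-rank")
        np.testing.assert_array_equal(out.values[:, 0], [1, 2, 3, 4, 5])
        X2 = _matrix(np.array([[2.0], [2.0], [5.0]]))
        out2 = rank_transform(X2, mode="average-rank")
        np.testing.assert_array_equal(out2.values[:, 0], [1.5, 1.5, 3.0])

    def test_standardized_mode_zero_mean_unit_variance(self, rng):
        X = _matrix(rng.normal(size=(30, 4)))
        out = rank_transform(X, mode="standardized")
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_inverse_normal_blom_scores(self):
        X = _matrix(np.arange(1.0, 102.0).reshape(-1, 1))
        out = rank_transform(X, mode="inverse-normal")
        col = out.values[:, 0]
        np.testing.assert_allclose(col, -col[::-1], atol=1e-12)  # symmetric
        expected_max = NormalDist().inv_cdf((101 - 0.375) / 101.25)
        assert col.max() == pytest.approx(expected_max, rel=1e-9)

    def test_constant_feature_rejected_in_inverse_normal(self):
        X = _matrix(np.ones((6, 2)))
        with pytest.raises(ComputationError):
            rank_transform(X, mode="inverse-normal")

    def test_invariant_to_monotone_transform(self, rng):
        data = rng.uniform(0.5, 2.0, size=(25, 3))
        a = rank_transform(_matrix(data), mode="standardized")
        b = rank_transform(_matrix(np.exp(2.0 * data)), mode="standardized")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestPcaBatchCheck:
    def test_planted_batch_shift_detected_then_removed(self):
        detected = removed = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            X, meta = _batch_shifted(rng, n_per=30, p=10, delta=1.5)
            before = pca_batch_check(X, meta)
            detected += before.loc[0, "p"] < 0.001
            corrected, _ = combat_correct(X, meta, preserve_group=False)
            after = pca_batch_check(corrected, meta)
            removed += after.loc[0, "p"] > 0.05
        assert detected == 20
        assert removed >= 18

    def test_null_batch_pvalues_roughly_uniform(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(900 + seed)
            X = _matrix(rng.normal(size=(40, 8)))
            meta = _meta([f"b{(i % 4) + 1}" for i in range(40)])
            ps.append(pca_batch_check(X, meta).loc[0, "p"])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_samples(self):
        X = _matrix(np.ones((2, 3)))
        with pytest.raises(ValidationError):
            pca_batch_check(X, _meta(["b1", "b1"]))


def test_pipeline_order_on_simulated_cohort():
    """Full chain runs on a simulated cohort and clears the batch signal."""
    cfg = SimulationConfig(n_control=40, n_case=40, batch_shift=0.6,
                           batch_scale=1.3, seed=2)
    X, meta = simulate_glycome(cfg)
    assert pca_batch_check(X, meta).loc[0, "p"] < 0.05
    corrected, _ = combat_correct(X, meta)
    normalized, factors = median_quotient_normalize(
        corrected if (corrected.values > 0).all() else X)
    ranked = rank_transform(normalized)
    assert ranked.compositional is False
    assert pca_batch_check(ranked, meta).loc[0, "p"] > 0.01
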