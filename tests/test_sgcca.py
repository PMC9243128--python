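import numpy as np
import pandas as pd
import pytest

from glycoblock.errors import ValidationError
from glycoblock.sgcca import (BlockSet, fit_sgcca, full_design, rank_loadings,
                              transform)


def _blockset(rng, n, ps, names=None):
    names = names or [f"B{i}" for i in range(len(ps))]
    frames = {name: pd.DataFrame(rng.normal(size=(n, p)),
                                 index=[f"S{i}" for i in range(n)],
                                 columns=[f"{name}v{j}" for j in range(p)])
              for name, p in zip(names, ps)}
    return BlockSet.from_frames(frames)


def _grid_max_objective(X1, X2, step_deg=0.1):
    """Exhaustive search of cov(X1 a1, X2 a2) over unit-circle angle pairs."""
    n = X1.shape[0]
    M = X1.T @ X2 / (n - 1)
    ang = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    A = np.column_stack([np.cos(ang), np.sin(ang)])   # candidate a1 (and a2)
    vals = (A @ M) @ A.T
    return float(vals.max())


class TestFitBasics:
    def test_two_perfectly_aligned_univariate_blocks(self, rng):
        x = rng.normal(size=25)
        frames = {"a": pd.DataFrame({"v": x}), "b": pd.DataFrame({"w": x})}
        blocks = BlockSet.from_frames(frames)
        model = fit_sgcca(blocks, n_dims=1)
        assert model.loadings["a"][0, 0] == pytest.approx(1.0)
        assert model.loadings["b"][0, 0] == pytest.approx(1.0)
        # scaled identical columns: objective = var of the scaled column = 1
        assert model.objective(0) == pytest.approx(2.0)  # both (i,h) orderings

    def test_design_validation(self, rng):
        blocks = _blockset(rng, 10, [3, 2])
        bad = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError):
            fit_sgcca(blocks, design=bad)
        with pytest.raises(ValidationError):
            fit_sgcca(blocks, design=np.array([[0.0, 2.0], [2.0, 0.0]]))

    def test_keepx_out_of_range(self, rng):
        blocks = _blockset(rng, 10, [3, 2])
        with pytest.raises(ValidationError):
            fit_sgcca(blocks, keepx={"B0": 5})


class TestOracles:
    @pytest.mark.parametrize("seed", range(50))
    def test_no_sparsity_matches_cross_covariance_svd(self, seed):
        """J=2, full design, no sparsity: the dimension-1 loadings are the
        leading singular vectors of X1' X2 (up to sign)."""
        rng = np.random.default_rng(seed)
        blocks = _blockset(rng, 20, [4, 3])
        # tight tolerance: near-degenerate singular gaps converge slowly
        model = fit_sgcca(blocks, n_dims=1, tol=1e-12, max_iter=20000)
        u, _, vt = np.linalg.svd(blocks.blocks["B0"].T @ blocks.blocks["B1"])
        a1, a2 = model.loadings["B0"][:, 0], model.loadings["B1"][:, 0]
        assert min(np.abs(a1 - u[:, 0]).max(), np.abs(a1 + u[:, 0]).max()) < 1e-6
        assert min(np.abs(a2 - vt[0]).max(), np.abs(a2 + vt[0]).max()) < 1e-6

    @pytest.mark.parametrize("seed", range(50))
    def test_objective_matches_exhaustive_grid(self, seed):
        """J=2, P=2 per block, N=6: achieved objective within 1e-3 of a
        0.1-degree grid search over unit-circle loading pairs."""
        rng = np.random.default_rng(1000 + seed)
        blocks = _blockset(rng, 6, [2, 2])
        model = fit_sgcca(blocks, keepx=2, n_dims=1, tol=1e-10, max_iter=500)
        grid_best = _grid_max_objective(blocks.blocks["B0"], blocks.blocks["B1"])
        achieved = model.objective(0) / 2.0  # objective counts both orderings
        assert achieved >= grid_best - 1e-3


class TestInvariantsAndConstraints:
    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_ascent_unit_norm_and_cardinality(self, seed):
        rng = np.random.default_rng(seed)
        blocks = _blockset(rng, 30, [8, 6, 4])
        keepx = {"B0": 3, "B1": 2, "B2": 4}
        model = fit_sgcca(blocks, keepx=keepx, n_dims=2)
        for trace in model.objective_trace:
            assert (np.diff(trace) >= -1e-9).all()
        for j, kx in keepx.items():
            for d in range(2):
                a = model.loadings[j][:, d]
                assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-8)
                assert np.count_nonzero(a) <= kx
                assert a[np.argmax(np.abs(a))] > 0  # sign convention

    def test_deflation_orthogonality(self, rng):
        blocks = _blockset(rng, 25, [6, 5])
        model = fit_sgcca(blocks, n_dims=3)
        for j in model.block_names:
            X = blocks.blocks[j].copy()
            for d in range(model.n_dims):
                s = model.scores[j][:, d]
                X = X - np.outer(s, model.regressors[j][:, d])
                assert np.abs(s @ X).max() < 1e-8

    def test_permutation_equivariance(self, rng):
        blocks = _blockset(rng, 20, [7, 4])
        model = fit_sgcca(blocks, keepx={"B0": 3}, n_dims=1)
        perm = rng.permutation(7)
        frames = {"B0": pd.DataFrame(blocks.blocks["B0"][:, perm],
                                     columns=[f"B0v{j}" for j in perm]),
                  "B1": pd.DataFrame(blocks.blocks["B1"],
                                     columns=[f"B1v{j}" for j in range(4)])}
        model_p = fit_sgcca(BlockSet.from_frames(frames), keepx={"B0": 3}, n_dims=1)
        np.testing.assert_allclose(model_p.loadings["B0"][:, 0],
                                   model.loadings["B0"][perm, 0], atol=1e-8)

    def test_l1_bound_mode_constrains_norm(self, rng):
        blocks = _blockset(rng, 30, [10, 6])
        model = fit_sgcca(blocks, l1_bounds={"B0": 1.5, "B1": 1.5}, n_dims=1)
        for j in ("B0", "B1"):
            a = model.loadings[j][:, 0]
            assert np.abs(a).sum() <= 1.5 + 1e-6
            assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-8)
        for trace in model.objective_trace:
            assert (np.diff(trace) >= -1e-9).all()


class TestTransform:
    def test_training_scores_reproduced(self, rng):
        blocks = _blockset(rng, 20, [5, 4])
        model = fit_sgcca(blocks, keepx={"B0": 3}, n_dims=2)
        scores = transform(model, blocks)
        for j in model.block_names:
            np.testing.assert_allclose(scores[j], model.scores[j], atol=1e-10)

    def test_duplicated_new_samples_get_duplicated_scores(self, rng):
        blocks = _blockset(rng, 15, [5, 4])
        model = fit_sgcca(blocks, n_dims=2)
        frames = {j: pd.DataFrame(
            np.vstack([blocks.blocks[j], blocks.blocks[j][:3]])
            * model.train_blocks.scales[j] + model.train_blocks.centers[j],
            columns=model.var_names[j]) for j in model.block_names}
        scaled = model.train_blocks.apply_scaling(frames)
        scores = transform(model, scaled)
        for j in model.block_names:
            np.testing.assert_allclose(scores[j][15:], scores[j][:3], atol=1e-8)

    def test_panel_mismatch_rejected(self, rng):
        blocks = _blockset(rng, 10, [3, 2])
        model = fit_sgcca(blocks, n_dims=1)
        bad = pd.DataFrame(np.zeros((2, 2)), columns=["B0v0", "B0v1"])
        with pytest.raises(ValidationError, match="B0v2"):
            model.train_blocks.apply_scaling({"B0": bad})


class TestRankLoadings:
    def test_keepx_10_returns_exactly_10(self, rng):
        blocks = _blockset(rng, 40, [39, 5])
        model = fit_sgcca(blocks, keepx={"B0": 10}, n_dims=1)
        table = rank_loadings(model, "B0", d=0, top=10)
        assert len(table) == 10
        mags = table["loading"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()  # most to least important

    def test_top_beyond_nonzero_truncates_with_note(self, rng):
        blocks = _blockset(rng, 20, [6, 3])
        model = fit_sgcca(blocks, keepx={"B0": 2}, n_dims=1)
        table = rank_loadings(model, "B0", d=0, top=5)
        assert len(table) == 2
        assert table.attrs["truncated"] is True

    def test_single_variable_block(self, rng):
        x = rng.normal(size=12)
        frames = {"a": pd.DataFrame({"v": x}),
                  "b": pd.DataFrame({"w": x + 0.1 * rng.normal(size=12)})}
        model = fit_sgcca(BlockSet.from_frames(frames), n_dims=1)
        table = rank_loadings(model, "a", d=0, top=1)
        assert table.iloc[0]["variable"] == "v"
        assert table.iloc[0]["loading"] == pytest.approx(1.0)

    def test_group_annotation_marks_higher_class(self, rng):
        n = 30
        g = np.array(["lo"] * 15 + ["hi"] * 15)
        v = np.where(g == "hi", 2.0, 0.0) + 0.1 * rng.normal(size=n)
        frames = {"a": pd.DataFrame({"v": v}),
                  "b": pd.DataFrame({"w": v + 0.1 * rng.normal(size=n)})}
        model = fit_sgcca(BlockSet.from_frames(frames), n_dims=1)
        table = rank_loadings(model, "a", d=0, top=1, groups=g)
        assert table.iloc[0]["higher_in"] == "hi"
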