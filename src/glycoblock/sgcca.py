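"""Sparse generalized canonical correlation analysis (sGCCA).

Given J centred/scaled blocks X^(1..J) observed on the same N samples and a
symmetric design matrix C with entries c_ih in [0, 1], sGCCA finds, for each
dimension d, block loading vectors a^(j) maximizing the design-weighted sum
of component covariances

    max  sum_{i != h} c_ih cov(X^(i) a^(i), X^(h) a^(h))
    s.t. ||a^(j)||_2 = 1  and a cardinality (keepX) or L1 bound per block,

by block-coordinate ascent: for each block in turn the gradient direction
z^(j) = X^(j)T sum_{h != j} c_jh X^(h) a^(h) is soft-thresholded to the
requested cardinality, renormalized to unit L2 norm, and the cycle repeats
until the largest loading change falls below ``tol``.  After convergence
each block is deflated by regressing out its own component score, and the
next dimension is fitted on the residual matrices.

Covariances use the 1/(N-1) convention.  Loadings are sign-fixed so the
largest-magnitude entry of each vector is positive, which makes results
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glycoblock.errors import ComputationError, ValidationError

__all__ = [
    "BlockSet",
    "SgccaModel",
    "full_design",
    "fit_sgcca",
    "transform",
    "rank_loadings",
]


@dataclass
class BlockSet:
    """J matrices sharing sample order, with centring/scaling parameters.

    Build from raw per-block DataFrames with :meth:`from_frames`, which
    centres each column to mean zero and scales to unit variance and
    remembers the parameters so held-out data can be placed on the training
    scale with :meth:`apply_scaling`.
    """

    blocks: dict[str, np.ndarray]
    var_names: dict[str, tuple[str, ...]]
    sample_ids: tuple[str, ...]
    centers: dict[str, np.ndarray] = field(default_factory=dict)
    scales: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name, mat in self.blocks.items():
            mat = np.asarray(mat, dtype=float)
            self.blocks[name] = mat
            if mat.shape[0] != n:
                raise ValidationError(f"block {name!r} has {mat.shape[0]} rows, expected {n}")
            if mat.shape[1] != len(self.var_names[name]):
                raise ValidationError(f"block {name!r} columns do not match its variable names")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.blocks)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frames(cls, frames: Mapping[str, pd.DataFrame], scale: bool = True) -> "BlockSet":
        names = list(frames)
        if not names:
            raise ValidationError("need at least one block")
        index = frames[names[0]].index
        for name in names[1:]:
            if not frames[name].index.equals(index):
                raise ValidationError(f"block {name!r} sample order differs from {names[0]!r}")
        blocks, var_names, centers, scales = {}, {}, {}, {}
        for name in names:
            mat = frames[name].to_numpy(dtype=float)
            c = mat.mean(axis=0)
            s = mat.std(axis=0, ddof=1)
            if scale and (s == 0).any():
                bad = [frames[name].columns[j] for j in np.where(s == 0)[0]]
                raise ComputationError(f"block {name!r} has constant variables: {bad}")
            if not scale:
                s = np.ones_like(s)
            blocks[name] = (mat - c) / s
            var_names[name] = tuple(map(str, frames[name].columns))
            centers[name] = c
            scales[name] = s
        return cls(blocks=blocks, var_names=var_names,
                   sample_ids=tuple(map(str, index)), centers=centers, scales=scales)

    def apply_scaling(self, frames: Mapping[str, pd.DataFrame]) -> "BlockSet":
        """Scale new data with this set's stored centring/scaling.

        Only the blocks present in ``frames`` are scaled (prediction omits
        the outcome block, for example).
        """
        blocks, var_names = {}, {}
        index = None
        for name in frames:
            if name not in self.names:
                raise ValidationError(f"unknown block {name!r}")
            df = frames[name]
            missing = [v for v in self.var_names[name] if v not in df.columns]
            if missing:
                raise ValidationError(f"block {name!r} is missing variables: {missing}")
            df = df[list(self.var_names[name])]
            if index is None:
                index = df.index
            blocks[name] = (df.to_numpy(dtype=float) - self.centers[name]) / self.scales[name]
            var_names[name] = self.var_names[name]
        return BlockSet(blocks=blocks, var_names=var_names,
                        sample_ids=tuple(map(str, index)),
                        centers=dict(self.centers), scales=dict(self.scales))


def full_design(names: Sequence[str]) -> pd.DataFrame:
    """All-connected design: ones off the diagonal, zeros on it."""
    J = len(names)
    C = np.ones((J, J)) - np.eye(J)
    return pd.DataFrame(C, index=list(names), columns=list(names))


def _validate_design(C: pd.DataFrame | np.ndarray, names: Sequence[str]) -> np.ndarray:
    if isinstance(C, pd.DataFrame):
        C = C.loc[list(names), list(names)].to_numpy(dtype=float)
    C = np.asarray(C, dtype=float)
    J = len(names)
    if C.shape != (J, J):
        raise ValidationError(f"design matrix must be {J}x{J}")
    if not np.allclose(C, C.T):
        raise ValidationError("design matrix must be symmetric")
    if (C < 0).any() or (C > 1).any():
        raise ValidationError("design entries must lie in [0, 1]")
    C = C.copy()
    np.fill_diagonal(C, 0.0)
    return C


def _sparse_direction(z: np.ndarray, keep: int) -> np.ndarray:
    """Exact maximizer of ``z . a`` subject to ``||a||_2 = 1`` and at most
    ``keep`` nonzero entries: keep the ``keep`` largest magnitudes of ``z``
    (ties broken toward lower index) and renormalize.

    Because this is the exact block-coordinate subproblem solution, cycling
    it over blocks can never decrease the sGCCA objective.
    """
    p = z.size
    norm = np.linalg.norm(z)
    if norm == 0:
        raise ComputationError("zero gradient direction: cannot normalize loading")
    if keep >= p:
        return z / norm
    order = np.lexsort((np.arange(p), -np.abs(z)))  # stable top-k
    out = np.zeros_like(z)
    out[order[:keep]] = z[order[:keep]]
    return out / np.linalg.norm(out)


def _l1_direction(z: np.ndarray, bound: float, tol: float = 1e-10) -> np.ndarray:
    """Exact maximizer of ``z . a`` subject to ``||a||_2 = 1`` and
    ``||a||_1 <= bound``: soft-threshold ``z`` at the level (found by
    bisection) where the normalized result meets the L1 bound."""
    if bound < 1.0:
        raise ValidationError("an L1 bound below 1 is infeasible on the unit sphere")
    norm = np.linalg.norm(z)
    if norm == 0:
        raise ComputationError("zero gradient direction: cannot normalize loading")
    a = z / norm
    if np.abs(a).sum() <= bound + tol:
        return a

    def normalized_l1(thr: float) -> tuple[float, np.ndarray]:
        shrunk = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
        nz = np.linalg.norm(shrunk)
        if nz == 0:
            return 1.0, shrunk
        shrunk = shrunk / nz
        return float(np.abs(shrunk).sum()), shrunk

    lo, hi = 0.0, float(np.abs(z).max())
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        l1, cand = normalized_l1(mid)
        if l1 > bound:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    l1, cand = normalized_l1(hi)
    return cand


@dataclass
class SgccaModel:
    """Fitted sGCCA model.

    ``loadings[j]`` is P_j x D; ``scores[j]`` is N x D with
    s_d^(j) = X_d^(j) a_d^(j) on the deflated training blocks;
    ``regressors[j]`` holds the deflation regression vectors
    c_d^(j) = X_d^(j)T s_d^(j) / (s_d^(j)T s_d^(j)) needed to replay the
    deflation on new data.
    """

    block_names: tuple[str, ...]
    var_names: dict[str, tuple[str, ...]]
    loadings: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    regressors: dict[str, np.ndarray]
    design: np.ndarray
    keepx: dict[str, tuple[int, ...]]
    n_dims: int
    tol: float
    max_iter: int
    n_iterations: tuple[int, ...] = ()
    objective_trace: tuple[tuple[float, ...], ...] = ()
    converged: tuple[bool, ...] = ()
    train_blocks: BlockSet | None = None

    def objective(self, d: int) -> float:
        """Final objective value at dimension d (0-based)."""
        return self.objective_trace[d][-1]

    def to_dict(self) -> dict:
        """JSON-serializable bundle (loadings, design, scaling, diagnostics)."""
        return {
            "block_names": list(self.block_names),
            "var_names": {k: list(v) for k, v in self.var_names.items()},
            "loadings": {k: v.tolist() for k, v in self.loadings.items()},
            "regressors": {k: v.tolist() for k, v in self.regressors.items()},
            "design": self.design.tolist(),
            "keepx": {k: list(v) for k, v in self.keepx.items()},
            "n_dims": self.n_dims,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "n_iterations": list(self.n_iterations),
            "converged": list(self.converged),
            "centers": {k: v.tolist() for k, v in (self.train_blocks.centers.items()
                                                   if self.train_blocks else {})},
            "scales": {k: v.tolist() for k, v in (self.train_blocks.scales.items()
                                                  if self.train_blocks else {})},
        }


def _objective(blocks: dict[str, np.ndarray], a: dict[str, np.ndarray],
               C: np.ndarray, names: Sequence[str]) -> float:
    n = next(iter(blocks.values())).shape[0]
    s = {j: blocks[j] @ a[j] for j in names}
    total = 0.0
    for i, ni in enumerate(names):
        for h, nh in enumerate(names):
            if i != h and C[i, h] != 0:
                total += C[i, h] * float(s[ni] @ s[nh]) / (n - 1)
    return total


def _resolve_keepx(keepx, names, blocks, D) -> dict[str, tuple[int, ...]]:
    out = {}
    for j in names:
        p = blocks[j].shape[1]
        if keepx is None:
            per_dim = (p,) * D
        elif isinstance(keepx, Mapping):
            val = keepx.get(j, p)
            per_dim = tuple(val) if np.ndim(val) else (int(val),) * D
        else:
            per_dim = (int(keepx),) * D
        if len(per_dim) != D:
            raise ValidationError(f"keepX for block {j!r} must have one entry per dimension")
        bad = [k for k in per_dim if not 1 <= k <= p]
        if bad:
            raise ValidationError(f"keepX for block {j!r} out of range [1, {p}]: {bad}")
        out[j] = per_dim
    return out


def fit_sgcca(blocks: BlockSet, design: pd.DataFrame | np.ndarray | None = None,
              keepx: Mapping[str, int | Sequence[int]] | int | None = None,
              n_dims: int = 2, tol: float = 1e-6, max_iter: int = 100,
              init: str = "svd", seed: int | None = None,
              l1_bounds: Mapping[str, float] | None = None,
              keep_train_blocks: bool = True) -> SgccaModel:
    """Fit sGCCA over ``n_dims`` dimensions by block-coordinate ascent.

    Parameters
    ----------
    blocks
        Prepared (centred/scaled) block set.
    design
        Symmetric J x J connection matrix; defaults to all-connected.
    keepx
        Cardinality constraint: scalar (all blocks), or mapping
        block -> int or per-dimension sequence.  ``None`` disables sparsity.
        Each block update keeps the keepX largest-magnitude entries of the
        gradient direction and renormalizes -- the exact subproblem
        maximizer, so the objective ascends monotonically.
    l1_bounds
        Alternative raw shrinkage parameterization: per-block L1 bound
        (>= 1) on the unit-norm loading, enforced by exact soft
        thresholding.  Mutually exclusive with ``keepx``.
    init
        ``"svd"`` (leading right singular vector per block, deterministic)
        or ``"random"`` with ``seed``.
    """
    names = blocks.names
    if design is None:
        design = full_design(names)
    C = _validate_design(design, names)
    n = blocks.n_samples
    min_rank = min(min(b.shape) for b in blocks.blocks.values())
    if not 1 <= n_dims <= min_rank:
        raise ValidationError(f"n_dims must be in [1, {min_rank}]")
    if keepx is not None and l1_bounds is not None:
        raise ValidationError("give either keepx or l1_bounds, not both")
    keepx_resolved = _resolve_keepx(keepx, names, blocks.blocks, n_dims)

    def constrain(z: np.ndarray, j: str, d: int) -> np.ndarray:
        if l1_bounds is not None and j in l1_bounds:
            return _l1_direction(z, float(l1_bounds[j]))
        return _sparse_direction(z, keepx_resolved[j][d])

    X = {j: blocks.blocks[j].copy() for j in names}
    loadings = {j: np.zeros((X[j].shape[1], n_dims)) for j in names}
    scores = {j: np.zeros((n, n_dims)) for j in names}
    regressors = {j: np.zeros((X[j].shape[1], n_dims)) for j in names}
    traces, iters, convs = [], [], []
    rng = np.random.default_rng(seed)

    for d in range(n_dims):
        a = {}
        for j in names:
            if init == "svd":
                # leading right singular vector of the (deflated) block
                _, _, vt = np.linalg.svd(X[j], full_matrices=False)
                v = vt[0]
            elif init == "random":
                v = rng.standard_normal(X[j].shape[1])
            else:
                raise ValueError(f"unknown init {init!r}")
            # project the initial direction onto the constraint set so the
            # recorded objective trajectory starts from a feasible point
            a[j] = constrain(v, j, d)

        trace = [_objective(X, a, C, names)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            max_change = 0.0
            for ji, j in enumerate(names):
                inner = np.zeros(n)
                for hi, h in enumerate(names):
                    if hi != ji and C[ji, hi] != 0:
                        inner += C[ji, hi] * (X[h] @ a[h])
                z = X[j].T @ inner
                if not z.any():
                    continue  # disconnected or orthogonal block: keep current
                new = constrain(z, j, d)
                max_change = max(max_change, float(np.max(np.abs(new - a[j]))))
                a[j] = new
            trace.append(_objective(X, a, C, names))
            if max_change < tol:
                converged = True
                break
        traces.append(tuple(trace))
        iters.append(it)
        convs.append(converged)

        # sign convention: largest-magnitude entry of each loading positive
        for j in names:
            top = int(np.argmax(np.abs(a[j])))
            if a[j][top] < 0:
                a[j] = -a[j]

        for j in names:
            s = X[j] @ a[j]
            ss = float(s @ s)
            c = (X[j].T @ s) / ss if ss > 0 else np.zeros(X[j].shape[1])
            loadings[j][:, d] = a[j]
            scores[j][:, d] = s
            regressors[j][:, d] = c
            X[j] = X[j] - np.outer(s, c)

    return SgccaModel(
        block_names=names, var_names=dict(blocks.var_names),
        loadings=loadings, scores=scores, regressors=regressors,
        design=C, keepx=keepx_resolved, n_dims=n_dims, tol=tol, max_iter=max_iter,
        n_iterations=tuple(iters), objective_trace=tuple(traces),
        converged=tuple(convs),
        train_blocks=blocks if keep_train_blocks else None,
    )


def transform(model: SgccaModel, new_blocks: BlockSet) -> dict[str, np.ndarray]:
    """Component scores for new samples, replaying the training deflation.

    ``new_blocks`` must be on the training scale (use
    ``model.train_blocks.apply_scaling``).  Returns per block an
    N_new x D score matrix.
    """
    out = {}
    for j in model.block_names:
        if j not in new_blocks.blocks:
            raise ValidationError(f"missing block {j!r}")
        if new_blocks.var_names[j] != model.var_names[j]:
            missing = [v for v in model.var_names[j] if v not in new_blocks.var_names[j]]
            raise ValidationError(f"block {j!r} variable panel mismatch; missing {missing}")
        Xj = new_blocks.blocks[j].copy()
        s_mat = np.zeros((Xj.shape[0], model.n_dims))
        for d in range(model.n_dims):
            s = Xj @ model.loadings[j][:, d]
            s_mat[:, d] = s
            Xj = Xj - np.outer(s, model.regressors[j][:, d])
        out[j] = s_mat
    return out


def rank_loadings(model: SgccaModel, block: str, d: int = 0, top: int = 10,
                  groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Top-|loading| variables of one block and dimension.

    Returns a table ordered most-to-least important with the signed
    loading; when per-sample class ``groups`` are given (training order),
    each variable is annotated with the class whose mean raw value is
    higher -- the usual loading-plot colour code.
    """
    if block not in model.block_names:
        raise ValidationError(f"unknown block {block!r}")
    a = model.loadings[block][:, d]
    nz = np.where(a != 0)[0]
    order = nz[np.argsort(-np.abs(a[nz]), kind="stable")]
    truncated = top > order.size
    order = order[:min(top, order.size)]
    rows = []
    for idx in order:
        row = {"variable": model.var_names[block][idx], "loading": float(a[idx])}
        if groups is not None:
            if model.train_blocks is None:
                raise ValidationError("group annotation needs stored training blocks")
            groups_arr = np.asarray(groups, dtype=object)
            col = model.train_blocks.blocks[block][:, idx]
            means = {g: float(col[groups_arr == g].mean()) for g in pd.unique(groups_arr)}
            row["higher_in"] = max(means, key=means.get)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["truncated"] = truncated
    return df
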