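"""Supervised multi-block discriminant wrapper (DIABLO-style).

The class label enters the sGCCA fit as a dummy-coded outcome block, making
the shared components discriminative.  Prediction places held-out samples in
each block's component space and assigns the class of the nearest training
class centroid; block calls are combined by a vote weighted by how strongly
each block's training components correlate with the outcome components.
Performance is summarised by stratified train/test splits, K-fold
cross-validation (balanced error rate) and the rank-based AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glycoblock.errors import ComputationError, ValidationError
from glycoblock.sgcca import BlockSet, SgccaModel, fit_sgcca, full_design, transform

__all__ = [
    "OUTCOME_BLOCK",
    "discriminant_design",
    "DiabloModel",
    "make_outcome_block",
    "fit_diablo",
    "split_train_test",
    "predict",
    "auc",
    "cross_validate",
    "ClassifierReport",
]

OUTCOME_BLOCK = "outcome"

DISTANCES = ("centroid-dist", "max-dist", "mahalanobis-dist")


def discriminant_design(data_blocks: Sequence[str], data_data: float = 0.1,
                        data_outcome: float = 1.0) -> pd.DataFrame:
    """Default supervised design: data blocks weakly connected to each
    other (0.1) and fully connected to the outcome block.

    Down-weighting the data-data connections keeps the components focused
    on discrimination instead of the dominant inter-block covariance."""
    names = list(data_blocks) + [OUTCOME_BLOCK]
    J = len(names)
    C = np.full((J, J), data_data)
    C[-1, :] = data_outcome
    C[:, -1] = data_outcome
    np.fill_diagonal(C, 0.0)
    return pd.DataFrame(C, index=names, columns=names)


def make_outcome_block(labels: Sequence[str]) -> pd.DataFrame:
    """Dummy indicator matrix (one column per class) from group labels."""
    labels = pd.Series(list(labels), dtype=str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("outcome needs at least two classes")
    return pd.DataFrame({c: (labels == c).astype(float).to_numpy() for c in classes},
                        index=labels.index)


@dataclass
class DiabloModel:
    """sGCCA model with an outcome block plus everything prediction needs."""

    sgcca: SgccaModel
    classes: tuple[str, ...]
    labels: tuple[str, ...]
    centroids: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    block_weights: dict[str, float] = field(default_factory=dict)

    @property
    def data_blocks(self) -> tuple[str, ...]:
        return tuple(b for b in self.sgcca.block_names if b != OUTCOME_BLOCK)


@dataclass
class ClassifierReport:
    per_block: dict[str, np.ndarray]        # block -> predicted class labels
    ensemble: np.ndarray                    # predicted class labels
    distances: dict[str, np.ndarray]        # block -> n x n_classes distances
    scores: np.ndarray                      # continuous discriminant score
    classes: tuple[str, ...]
    distance: str


def fit_diablo(frames: Mapping[str, pd.DataFrame], labels: Sequence[str],
               design: pd.DataFrame | np.ndarray | None = None,
               keepx: Mapping[str, int | Sequence[int]] | int | None = None,
               n_dims: int = 2, **fit_kwargs) -> DiabloModel:
    """Fit the supervised model: data blocks plus a dummy outcome block.

    ``frames`` maps block name -> samples x variables DataFrame (shared
    index order); ``labels`` are the per-sample classes in the same order.
    ``keepx`` applies to the data blocks; the outcome block is never
    sparsified.
    """
    if OUTCOME_BLOCK in frames:
        raise ValidationError(f"{OUTCOME_BLOCK!r} is a reserved block name")
    first = next(iter(frames.values()))
    y = make_outcome_block(labels)
    y.index = first.index
    classes = tuple(y.columns)
    all_frames = dict(frames)
    all_frames[OUTCOME_BLOCK] = y
    blocks = BlockSet.from_frames(all_frames)

    if design is None:
        design = discriminant_design(list(frames))
    if keepx is not None and not isinstance(keepx, Mapping):
        keepx = {b: int(keepx) for b in frames}
    model = fit_sgcca(blocks, design=design, keepx=keepx, n_dims=n_dims, **fit_kwargs)

    labels_arr = np.asarray(list(labels), dtype=object)
    centroids: dict[str, dict[str, np.ndarray]] = {}
    for b in frames:
        centroids[b] = {c: model.scores[b][labels_arr == c].mean(axis=0) for c in classes}
    weights = {}
    for b in frames:
        cors = []
        for d in range(model.n_dims):
            sx = model.scores[b][:, d]
            sy = model.scores[OUTCOME_BLOCK][:, d]
            if sx.std() > 0 and sy.std() > 0:
                cors.append(abs(float(np.corrcoef(sx, sy)[0, 1])))
        weights[b] = float(np.mean(cors)) if cors else 0.0
    return DiabloModel(sgcca=model, classes=classes,
                       labels=tuple(map(str, labels)), centroids=centroids,
                       block_weights=weights)


def split_train_test(labels: Sequence[str], fraction: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of sample positions.

    Returns index arrays (train, test).  Per class the train share is
    ``round(fraction * n_class)``; deterministic under ``seed``.
    """
    labels_arr = np.asarray(list(labels), dtype=object)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in sorted(set(labels_arr.tolist())):
        idx = np.where(labels_arr == c)[0]
        if idx.size < 5:
            raise ValidationError(f"class {c!r} has fewer than 5 samples")
        perm = rng.permutation(idx)
        n_train = int(round(fraction * idx.size))
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(test, dtype=int))


def _block_distances(scores_new: np.ndarray, cents: dict[str, np.ndarray],
                     classes: Sequence[str], distance: str,
                     train_scores: np.ndarray | None = None,
                     train_labels: np.ndarray | None = None) -> np.ndarray:
    n = scores_new.shape[0]
    out = np.zeros((n, len(classes)))
    if distance in ("centroid-dist", "max-dist"):
        for ci, c in enumerate(classes):
            out[:, ci] = np.linalg.norm(scores_new - cents[c][None, :], axis=1)
    elif distance == "mahalanobis-dist":
        for ci, c in enumerate(classes):
            resid = train_scores[train_labels == c] - cents[c][None, :]
            cov = (resid.T @ resid) / max(resid.shape[0] - 1, 1)
            cov += 1e-10 * np.eye(cov.shape[0])
            inv = np.linalg.inv(cov)
            diff = scores_new - cents[c][None, :]
            out[:, ci] = np.sqrt(np.einsum("ij,jk,ik->i", diff, inv, diff))
    else:
        raise ValidationError(f"unknown distance {distance!r}; choose from {DISTANCES}")
    return out


def predict(model: DiabloModel, frames: Mapping[str, pd.DataFrame],
            distance: str = "centroid-dist") -> ClassifierReport:
    """Classify new samples.

    Per data block, component scores of the new samples are compared with
    the training class centroids under the chosen distance; the ensemble
    call is a block-weighted vote.  The continuous ``scores`` (distance to
    the first class minus distance to the second, weight-summed over
    blocks) order samples for AUC: larger means more like the second class.
    """
    sg = model.sgcca
    train_labels = np.asarray(model.labels, dtype=object)
    new_scaled = sg.train_blocks.apply_scaling(
        {b: frames[b] for b in model.data_blocks})
    # outcome block is absent at prediction time; transform data blocks only
    comp = {}
    for b in model.data_blocks:
        Xj = new_scaled.blocks[b].copy()
        s_mat = np.zeros((Xj.shape[0], sg.n_dims))
        for d in range(sg.n_dims):
            s = Xj @ sg.loadings[b][:, d]
            s_mat[:, d] = s
            Xj = Xj - np.outer(s, sg.regressors[b][:, d])
        comp[b] = s_mat

    n_new = next(iter(comp.values())).shape[0]
    dists: dict[str, np.ndarray] = {}
    per_block: dict[str, np.ndarray] = {}
    votes = np.zeros((n_new, len(model.classes)))
    cont = np.zeros(n_new)
    for b in model.data_blocks:
        dist_b = _block_distances(comp[b], model.centroids[b], model.classes, distance,
                                  train_scores=sg.scores[b], train_labels=train_labels)
        dists[b] = dist_b
        calls = np.argmin(dist_b, axis=1)
        per_block[b] = np.array([model.classes[c] for c in calls], dtype=object)
        w = model.block_weights.get(b, 0.0)
        for ci in range(len(model.classes)):
            votes[calls == ci, ci] += w
        cont += w * (dist_b[:, 0] - dist_b[:, 1])
    ensemble_idx = np.argmax(votes, axis=1)
    ensemble = np.array([model.classes[c] for c in ensemble_idx], dtype=object)
    return ClassifierReport(per_block=per_block, ensemble=ensemble, distances=dists,
                            scores=cont, classes=model.classes, distance=distance)


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction.

    ``labels`` are binary (the larger/second class is 'positive'); the AUC
    is the probability a random positive outranks a random negative, with
    ties counted half.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(list(labels))
    classes = np.unique(labels_arr)
    if classes.size != 2:
        raise ValidationError(f"AUC needs exactly two classes, got {classes.tolist()}")
    pos = labels_arr == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(set(labels.tolist())):
        idx = rng.permutation(np.where(labels == c)[0])
        for i, sample in enumerate(idx):
            folds[i % k].append(int(sample))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(frames: Mapping[str, pd.DataFrame], labels: Sequence[str],
                   folds: int = 5, repeats: int = 1, seed: int = 0,
                   keepx: Mapping[str, int] | int | None = None,
                   keepx_grid: Sequence[int] | None = None,
                   n_dims: int = 2, distance: str = "centroid-dist",
                   design: pd.DataFrame | None = None) -> dict:
    """Repeated stratified K-fold CV of the supervised model.

    Returns per-fold balanced error rates and their mean; with a
    ``keepx_grid`` the grid value minimizing the mean balanced error is
    chosen (ties toward the smaller keepX) and reported.
    """
    labels_arr = np.asarray(list(labels), dtype=object)
    class_counts = pd.Series(labels_arr).value_counts()
    if folds < 2:
        raise ValidationError("need at least 2 folds")
    if folds > class_counts.min():
        raise ValidationError(
            f"folds={folds} exceeds the smallest class size {class_counts.min()}")

    def run(keepx_val) -> tuple[list[float], float]:
        errors = []
        for rep in range(repeats):
            rng = np.random.default_rng(seed + rep)
            for fold in _stratified_folds(labels_arr, folds, rng):
                test_mask = np.zeros(labels_arr.size, dtype=bool)
                test_mask[fold] = True
                tr_frames = {b: df.iloc[~test_mask] for b, df in frames.items()}
                te_frames = {b: df.iloc[test_mask] for b, df in frames.items()}
                model = fit_diablo(tr_frames, labels_arr[~test_mask], keepx=keepx_val,
                                   n_dims=n_dims, design=design)
                rep_pred = predict(model, te_frames, distance=distance)
                truth = labels_arr[test_mask]
                per_class = []
                for c in model.classes:
                    mask = truth == c
                    if mask.any():
                        per_class.append(float((rep_pred.ensemble[mask] != c).mean()))
                errors.append(float(np.mean(per_class)))
        return errors, float(np.mean(errors))

    if keepx_grid is not None:
        results = {}
        for kx in sorted(keepx_grid):
            _, mean_err = run(int(kx))
            results[int(kx)] = mean_err
        best = min(results, key=lambda kx: (results[kx], kx))
        errors, mean_err = run(best)
        return {"fold_errors": errors, "mean_balanced_error": mean_err,
                "chosen_keepx": best, "grid_errors": results}
    errors, mean_err = run(keepx)
    return {"fold_errors": errors, "mean_balanced_error": mean_err}
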