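"""Preprocessing chain: empirical-Bayes batch correction, median quotient
normalization and rank transformation, plus a PCA-based batch diagnostic.

The canonical stage order is batch correction -> median quotient
normalization -> rank transform; each stage is independent so the order is
the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from glycoblock.datamodel import GlycanPeakMatrix, SampleMetadata
from glycoblock.errors import ComputationError, ValidationError

__all__ = [
    "BatchModel",
    "combat_correct",
    "median_quotient_normalize",
    "rank_transform",
    "pca_batch_check",
]


@dataclass
class BatchModel:
    """Fitted location/scale batch model.

    Per feature: the grand standardization parameters; per batch x feature:
    raw location/scale estimates (``gamma_hat``, ``delta2_hat``) and their
    empirical-Bayes shrunk counterparts (``gamma_star``, ``delta2_star``)
    under a normal prior on locations and an inverse-gamma prior on scales,
    hyperparameters fitted by method of moments.
    """

    batches: tuple[str, ...]
    feature_ids: tuple[str, ...]
    stand_mean: np.ndarray          # n x p standardization mean (incl. covariates)
    var_pooled: np.ndarray          # p
    gamma_hat: np.ndarray           # B x p
    delta2_hat: np.ndarray          # B x p
    gamma_star: np.ndarray          # B x p
    delta2_star: np.ndarray         # B x p
    gamma_bar: np.ndarray           # B  (normal prior means)
    tau2: np.ndarray                # B  (normal prior variances)
    a_prior: np.ndarray             # B  (inverse-gamma shape)
    b_prior: np.ndarray             # B  (inverse-gamma rate)
    iterations: tuple[int, ...] = ()


def _eb_fixed_point(z_batch: np.ndarray, gamma_hat: np.ndarray, delta2_hat: np.ndarray,
                    gamma_bar: float, tau2: float, a: float, b: float,
                    tol: float = 1e-6, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the conditional posterior means of (gamma*, delta2*) to a fixed point."""
    n_b = z_batch.shape[0]
    g = gamma_hat.copy()
    d2 = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n_b * tau2 * gamma_hat + d2 * gamma_bar) / (n_b * tau2 + d2)
        ssr = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (0.5 * ssr + b) / (n_b / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g)), np.max(np.abs(d2_new - d2)))
        g, d2 = g_new, d2_new
        if change < tol:
            break
    return g, d2, it


def combat_correct(X: GlycanPeakMatrix, meta: SampleMetadata,
                   preserve_group: bool = True,
                   tol: float = 1e-6) -> tuple[GlycanPeakMatrix, BatchModel]:
    """Remove plate-wise location/scale artifacts by parametric empirical Bayes.

    Each feature is standardized against its grand mean and pooled variance
    (with the group effect kept in the mean model when ``preserve_group`` so
    biological signal is not absorbed into batch estimates), per-batch
    location and scale estimates are shrunk toward batch-level priors
    (normal / inverse-gamma, moment-matched), and the data are
    back-transformed.  With a single batch the data are returned unchanged.

    Returns the corrected matrix (``compositional`` cleared) and the fitted
    :class:`BatchModel`.
    """
    aligned = meta.aligned(X.sample_ids)
    batch_labels = aligned[meta.batch_col].astype(str).to_numpy()
    batches = tuple(dict.fromkeys(batch_labels))  # stable order of appearance
    n, p = X.values.shape

    variances = X.values.var(axis=0, ddof=1)
    zero_var = [X.peak_ids[j] for j in np.where(variances <= 0)[0]]
    if zero_var:
        raise ComputationError(f"zero-variance features: {zero_var}")

    counts = {b: int((batch_labels == b).sum()) for b in batches}
    small = [b for b, c in counts.items() if c < 2]
    if small and len(batches) > 1:
        raise ValidationError(f"batches with fewer than 2 samples: {small}")

    data = X.values.astype(float)

    if len(batches) == 1:
        model = BatchModel(
            batches=batches, feature_ids=X.peak_ids,
            stand_mean=np.tile(data.mean(axis=0), (n, 1)),
            var_pooled=variances,
            gamma_hat=np.zeros((1, p)), delta2_hat=np.ones((1, p)),
            gamma_star=np.zeros((1, p)), delta2_star=np.ones((1, p)),
            gamma_bar=np.zeros(1), tau2=np.ones(1),
            a_prior=np.ones(1), b_prior=np.ones(1), iterations=(0,),
        )
        return X.with_values(data.copy(), compositional=False), model

    batch_design = np.column_stack([(batch_labels == b).astype(float) for b in batches])
    design_parts = [batch_design]
    if preserve_group:
        group = aligned[meta.group_col].astype(str).to_numpy()
        levels = list(dict.fromkeys(group))
        for lev in levels[1:]:  # drop-first coding
            design_parts.append((group == lev).astype(float)[:, None])
    design = np.hstack(design_parts)

    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    n_batch = batch_design.sum(axis=0)
    grand_mean = (n_batch / n) @ beta[:len(batches)]
    stand_mean = np.tile(grand_mean, (n, 1))
    if design.shape[1] > len(batches):
        stand_mean = stand_mean + design[:, len(batches):] @ beta[len(batches):]

    resid = data - design @ beta
    var_pooled = (resid ** 2).sum(axis=0) / n
    if (var_pooled <= 0).any():
        bad = [X.peak_ids[j] for j in np.where(var_pooled <= 0)[0]]
        raise ComputationError(f"zero pooled variance for features: {bad}")

    z = (data - stand_mean) / np.sqrt(var_pooled)

    B = len(batches)
    gamma_hat = np.empty((B, p))
    delta2_hat = np.empty((B, p))
    gamma_star = np.empty((B, p))
    delta2_star = np.empty((B, p))
    gamma_bar = np.empty(B)
    tau2 = np.empty(B)
    a_prior = np.empty(B)
    b_prior = np.empty(B)
    iters = []

    for bi, b in enumerate(batches):
        mask = batch_labels == b
        zb = z[mask]
        gamma_hat[bi] = zb.mean(axis=0)
        delta2_hat[bi] = zb.var(axis=0, ddof=1)
        gamma_bar[bi] = gamma_hat[bi].mean()
        tau2[bi] = gamma_hat[bi].var(ddof=1)
        m = delta2_hat[bi].mean()
        s2 = delta2_hat[bi].var(ddof=1)
        if s2 <= 0:
            # degenerate (e.g. 2 features): flat prior, no scale shrinkage
            a_prior[bi] = 2.0
            b_prior[bi] = m
        else:
            a_prior[bi] = (2.0 * s2 + m ** 2) / s2
            b_prior[bi] = (m * s2 + m ** 3) / s2
        g_star, d2_star, it = _eb_fixed_point(
            zb, gamma_hat[bi], delta2_hat[bi],
            gamma_bar[bi], tau2[bi], a_prior[bi], b_prior[bi], tol=tol)
        gamma_star[bi], delta2_star[bi] = g_star, d2_star
        iters.append(it)

    adj = z.copy()
    for bi, b in enumerate(batches):
        mask = batch_labels == b
        adj[mask] = (z[mask] - gamma_star[bi][None, :]) / np.sqrt(delta2_star[bi][None, :])
    corrected = adj * np.sqrt(var_pooled) + stand_mean

    model = BatchModel(
        batches=batches, feature_ids=X.peak_ids, stand_mean=stand_mean,
        var_pooled=var_pooled, gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_star=gamma_star, delta2_star=delta2_star, gamma_bar=gamma_bar,
        tau2=tau2, a_prior=a_prior, b_prior=b_prior, iterations=tuple(iters),
    )
    return X.with_values(corrected, compositional=False), model


def median_quotient_normalize(
        X: GlycanPeakMatrix,
        reference: str | None = None,
) -> tuple[GlycanPeakMatrix, np.ndarray]:
    """Per-sample dilution correction by the median quotient to a reference.

    The reference spectrum is the feature-wise median across samples
    (default) or an explicit sample id.  Each sample's dilution factor is
    the median over features of value/reference; the sample is divided by
    its factor.  Requires strictly positive data.

    Returns the normalized matrix and the per-sample factors (in row order).
    """
    data = X.values
    if (data <= 0).any():
        rows, cols = np.where(data <= 0)
        cells = [(X.sample_ids[r], X.peak_ids[c]) for r, c in zip(rows[:10], cols[:10])]
        raise ValidationError(f"median quotient normalization needs positive values; "
                              f"offending cells: {cells}")
    if reference is None:
        ref = np.median(data, axis=0)
    else:
        if reference not in X.sample_ids:
            raise ValidationError(f"reference sample {reference!r} not found")
        ref = data[X.sample_ids.index(reference)]
    if (ref <= 0).any():
        raise ComputationError("reference spectrum has non-positive entries")
    factors = np.median(data / ref[None, :], axis=1)
    normalized = data / factors[:, None]
    return X.with_values(normalized, compositional=False), factors


def rank_transform(X: GlycanPeakMatrix, mode: str = "standardized") -> GlycanPeakMatrix:
    """Per-feature rank transformation.

    Modes
    -----
    ``average-rank``
        Ranks 1..n with ties averaged.
    ``standardized`` (default)
        Average ranks scaled to zero mean / unit variance per feature.
    ``inverse-normal``
        Blom scores: the standard normal quantile of ``(rank - 3/8)/(n + 1/4)``.

    Constant features are an error in the standardized and inverse-normal
    modes (the transform is undefined on all-ties columns).
    """
    if mode not in ("average-rank", "standardized", "inverse-normal"):
        raise ValueError(f"unknown rank mode {mode!r}")
    data = X.values
    n = data.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, data)
    if mode == "average-rank":
        out = ranks
    else:
        const = np.where(data.std(axis=0) == 0)[0]
        if const.size:
            raise ComputationError(
                f"constant features cannot be rank-transformed in mode {mode!r}: "
                f"{[X.peak_ids[j] for j in const]}")
        if mode == "standardized":
            out = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0, ddof=1)
        else:
            out = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return X.with_values(out, compositional=False)


def pca_batch_check(X: GlycanPeakMatrix, meta: SampleMetadata,
                    n_components: int = 5) -> pd.DataFrame:
    """Screen principal components for residual plate clustering.

    Centred SVD scores for the leading components are tested against batch
    with a Kruskal-Wallis one-way rank test.  Returns a table with one row
    per component: variance explained, H statistic and p-value.
    """
    n = X.n_samples
    if n < 3:
        raise ValidationError("PCA batch check needs at least 3 samples")
    batch_labels = meta.batches_for(X.sample_ids).astype(str)
    centred = X.values - X.values.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    var_explained = (s[:k] ** 2) / (s ** 2).sum()

    rows = []
    unique_batches = pd.unique(batch_labels)
    for c in range(k):
        if len(unique_batches) > 1:
            groups = [scores[batch_labels == b, c] for b in unique_batches]
            stat, p = stats.kruskal(*groups)
        else:
            stat, p = 0.0, 1.0
        rows.append({"component": c + 1, "variance_explained": float(var_explained[c]),
                     "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)
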