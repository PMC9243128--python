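"""Univariate group comparisons with Benjamini-Hochberg FDR control.

Implements the screening layer of the case/control analysis: chi-square
tests of independence for categorical factors, Student's t and
Mann-Whitney U tests for continuous measures, a Kolmogorov-Smirnov
normality check, BH adjustment within explicit test families, and
cluster-wise significance summaries (K features per cluster, k significant
at a level alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glycoblock.datamodel import GlycanPeakMatrix, SampleMetadata
from glycoblock.errors import ComputationError, ValidationError

__all__ = [
    "UnivariateResult",
    "ClusterSummary",
    "chi_square_independence",
    "students_t",
    "mann_whitney_u",
    "bh_adjust",
    "ks_normality",
    "screen_features",
]


@dataclass
class UnivariateResult:
    feature_id: str
    test: str
    statistic: float
    p: float
    df: float | None = None
    q: float | None = None
    group_summary: dict = field(default_factory=dict)


@dataclass
class ClusterSummary:
    cluster_id: str
    K: int
    k: int
    members: tuple[str, ...]


def chi_square_independence(table: np.ndarray | Sequence[Sequence[float]],
                            feature_id: str = "") -> UnivariateResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction is applied (the convention for tables larger
    than 2 x 2, and the one under which published demographic statistics
    are reproducible).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValidationError("contingency table must be 2-D")
    if (obs < 0).any():
        raise ValidationError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return UnivariateResult(feature_id=feature_id, test="chi-square",
                            statistic=float(stat), p=float(p), df=float(dof))


def students_t(x: Sequence[float], y: Sequence[float], variant: str = "pooled",
               feature_id: str = "") -> UnivariateResult:
    """Two-sample t test, pooled-variance ('Student's') by default.

    Degenerate inputs: zero variance in both groups with equal means gives
    t = 0, p = 1; zero variance with unequal means is an error.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            df = x.size + y.size - 2
            return UnivariateResult(feature_id, "student-t", 0.0, 1.0, df=float(df))
        raise ComputationError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    df = float(res.df) if hasattr(res, "df") else float(x.size + y.size - 2)
    return UnivariateResult(
        feature_id, "student-t" if variant == "pooled" else "welch-t",
        float(res.statistic), float(res.pvalue), df=df,
        group_summary={"mean_x": float(x.mean()), "sd_x": float(x.std(ddof=1)),
                       "mean_y": float(y.mean()), "sd_y": float(y.std(ddof=1))})


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   feature_id: str = "") -> UnivariateResult:
    """Mann-Whitney U test (min-U convention, two-sided).

    Exact enumeration is used for small tie-free samples (min group size
    below 8); otherwise the tie-corrected, continuity-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return UnivariateResult(
        feature_id, "mann-whitney-u", min(u1, u2), float(res.pvalue),
        group_summary={"median_x": float(np.median(x)), "median_y": float(np.median(y)),
                       "U1": u1, "U2": u2})


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ks_normality(x: Sequence[float], feature_id: str = "") -> UnivariateResult:
    """One-sample Kolmogorov-Smirnov test against a normal with estimated
    mean and SD.

    The p-value uses the asymptotic KS distribution and is approximate
    (anticonservative) because the parameters are estimated from the data.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValidationError("KS normality check needs at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ComputationError("constant vector: normality test undefined")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    res = UnivariateResult(feature_id, "ks-normality", float(stat), float(p))
    res.group_summary = {"approximate": True}
    return res


def screen_features(X: GlycanPeakMatrix, meta: SampleMetadata, alpha: float = 0.05,
                    clusters: Mapping[str, str] | None = None,
                    ) -> tuple[list[UnivariateResult], list[ClusterSummary]]:
    """Per-feature Mann-Whitney case/control screening with BH over the
    feature family, plus K/k significance counts per cluster.

    ``clusters`` maps feature id -> cluster id; absent means a single
    cluster containing every feature.  Cluster counts use the raw p at
    ``alpha`` (the convention for cluster-wise expression summaries);
    BH-adjusted q values are attached to each result.
    """
    lo, hi = meta.check_two_groups()
    groups = meta.groups_for(X.sample_ids).astype(str)
    mask_lo = groups == lo
    mask_hi = groups == hi
    results = []
    for j, fid in enumerate(X.peak_ids):
        res = mann_whitney_u(X.values[mask_lo, j], X.values[mask_hi, j], feature_id=fid)
        results.append(res)
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)

    if clusters is None:
        clusters = {fid: "all" for fid in X.peak_ids}
    unknown = [fid for fid in clusters if fid not in X.peak_ids]
    if unknown:
        raise ValidationError(f"cluster assignment references unknown features: {unknown}")
    by_cluster: dict[str, list[str]] = {}
    for fid in X.peak_ids:
        by_cluster.setdefault(str(clusters.get(fid, "unassigned")), []).append(fid)
    p_by_feature = {r.feature_id: r.p for r in results}
    summaries = [
        ClusterSummary(cluster_id=cid, K=len(members),
                       k=sum(p_by_feature[f] < alpha for f in members),
                       members=tuple(members))
        for cid, members in sorted(by_cluster.items())
    ]
    return results, summaries


def results_frame(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    """Tidy results table (feature, test, statistic, df, p, q)."""
    return pd.DataFrame([
        {"feature": r.feature_id, "test": r.test, "statistic": r.statistic,
         "df": r.df, "p": r.p, "q": r.q}
        for r in results
    ])
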