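"""Dissimilarities, ordination, and permutation statistics.

The statistical layer used downstream of the abundance tables: Bray-Curtis
dissimilarity with principal coordinate analysis (PCoA), the Hellinger
transform with principal component analysis (PCA), PERMANOVA (global and
pairwise with Benjamini-Hochberg adjustment), Welch's t-test, and Ward
clustering for heatmap row/column ordering.

PERMANOVA follows Anderson's formulation: with n samples in a groups,

    SS_total  = (1/n)   * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = ((SS_total - SS_within)/(a-1)) / (SS_within/(n-a))

and the p-value is the add-one permutation estimator
``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``, which can never be exactly 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import ValidationError

__all__ = [
    "OrdinationResult",
    "bray_curtis",
    "hellinger",
    "pcoa",
    "pca",
    "permanova",
    "pairwise_permanova",
    "welch_t",
    "ward_order",
]

logger = logging.getLogger(__name__)


def bray_curtis(abund: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarities between rows (samples).

    ``d[s, t] = sum |x_s - x_t| / sum (x_s + x_t)``; a pair of all-zero rows
    has an undefined ratio and is defined here as 0 (with a warning).
    """
    x = abund.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis requires nonnegative values")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        logger.warning("all-zero sample pair(s); their dissimilarity is set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=abund.index, columns=abund.index)


def hellinger(abund: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: ``h[s, f] = sqrt(x[s, f] / rowsum_s)``.

    Row sums of squares equal 1, so Euclidean distances between transformed
    rows are Hellinger distances between the raw compositions.
    """
    x = abund.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Hellinger transform requires nonnegative values")
    sums = x.sum(axis=1)
    if np.any(sums == 0):
        bad = abund.index[int(np.argmax(sums == 0))]
        raise ValidationError(f"sample {bad!r} has zero total abundance")
    return pd.DataFrame(
        np.sqrt(x / sums[:, None]), index=abund.index, columns=abund.columns
    )


@dataclass
class OrdinationResult:
    """Sample coordinates with eigenvalues and explained variance per axis."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: pd.Series  # one per axis, non-increasing (may be negative, PCoA)
    proportion_explained: pd.Series


def _axis_labels(k: int, prefix: str) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


def pcoa(d: pd.DataFrame, correction: str | None = None) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling) of a distance matrix.

    Eigendecomposition of the Gower-centered matrix ``-0.5 * J D^2 J``.
    Negative eigenvalues (non-Euclidean distances) are reported, never
    silently dropped; coordinates are returned only for positive-eigenvalue
    axes.  ``correction="cailliez"`` adds the smallest constant to all
    off-diagonal distances that makes the matrix Euclidean.
    """
    dm = d.to_numpy(dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if correction == "cailliez":
        dm = _cailliez(dm)
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    n = dm.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    labels = _axis_labels(int(pos.sum()), "PCo")
    total = eigvals.sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=labels),
        eigenvalues=pd.Series(eigvals, index=_axis_labels(n, "PCo")),
        proportion_explained=pd.Series(
            eigvals / total if total != 0 else np.zeros(n), index=_axis_labels(n, "PCo")
        ),
    )


def _cailliez(dm: np.ndarray) -> np.ndarray:
    """Smallest additive constant making a distance matrix Euclidean."""
    n = dm.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    d1 = -0.5 * j @ (dm**2) @ j
    d2 = -0.5 * j @ dm @ j
    block = np.block([[np.zeros((n, n)), 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    c = float(np.max(np.real(np.linalg.eigvals(block))))
    if c <= 0:
        return dm
    out = dm + c
    np.fill_diagonal(out, 0.0)
    return out


def pca(x: pd.DataFrame) -> OrdinationResult:
    """PCA via eigendecomposition of the covariance of column-centered data."""
    mat = x.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=0)
    n = mat.shape[0]
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (n - 1)
    coords = u * s
    labels = _axis_labels(len(eigvals), "PC")
    total = eigvals.sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=x.index, columns=labels),
        eigenvalues=pd.Series(eigvals, index=labels),
        proportion_explained=pd.Series(
            eigvals / total if total != 0 else np.zeros_like(eigvals), index=labels
        ),
    )


def _check_groups(groups: np.ndarray) -> list[np.ndarray]:
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    small = uniq[counts < 2]
    if len(small):
        raise ValidationError(f"group {small[0]!r} has fewer than 2 samples")
    return [np.asarray(groups == g) for g in uniq]


def _permanova_stats(
    d2: np.ndarray, labels: np.ndarray, perms: np.ndarray
) -> tuple[float, np.ndarray]:
    """Observed pseudo-F and the permutation distribution.

    ``perms`` is an (n_perm, n) array of permuted sample indices; the
    within-group sum of squares under each permutation is evaluated with a
    batched quadratic form per group.
    """
    n = d2.shape[0]
    uniq = np.unique(labels)
    a = len(uniq)
    ss_total = d2.sum() / (2.0 * n)

    def ss_within(label_rows: np.ndarray) -> np.ndarray:
        # label_rows: (m, n) array of labels; returns (m,) SS_within
        out = np.zeros(label_rows.shape[0])
        for g in uniq:
            mask = (label_rows == g).astype(float)
            n_g = mask[0].sum()
            out += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * n_g)
        return out

    ss_w_obs = float(ss_within(labels[None, :])[0])
    f_obs = ((ss_total - ss_w_obs) / (a - 1)) / (ss_w_obs / (n - a))
    ss_w_perm = ss_within(labels[perms])
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ss_w_perm) / (a - 1)) / (ss_w_perm / (n - a))
    return f_obs, f_perm


def permanova(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Global PERMANOVA; returns (pseudo-F, permutation p-value)."""
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    labels = np.asarray(list(groups))
    if len(labels) != d.shape[0]:
        raise ValidationError("groups must match the distance matrix")
    _check_groups(labels)
    d2 = d.to_numpy(dtype=float) ** 2
    rng = np.random.default_rng(seed)
    n = len(labels)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    f_obs, f_perm = _permanova_stats(d2, labels, perms)
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return float(f_obs), float(p)


def pairwise_permanova(
    d: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    fdr: bool = True,
) -> pd.DataFrame:
    """All pairwise PERMANOVAs with optional Benjamini-Hochberg adjustment.

    Pair order (and the per-pair permutation streams spawned from ``seed``)
    is deterministic: lexicographic on group labels.
    """
    labels = np.asarray(list(groups))
    _check_groups(labels)
    uniq = sorted(map(str, np.unique(labels)))
    rng = np.random.default_rng(seed)
    rows = []
    for i, ga in enumerate(uniq):
        for gb in uniq[i + 1 :]:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            mask = np.isin(labels.astype(str), [ga, gb])
            sub_d = d.iloc[mask, mask]
            f, p = permanova(sub_d, labels[mask], n_perm=n_perm, seed=sub_seed)
            rows.append({"group_a": ga, "group_b": gb, "pseudo_f": f, "p_value": p})
    table = pd.DataFrame(rows)
    if fdr and len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def permanova_null_calibration(
    n_sims: int = 1000,
    n_samples: int = 20,
    n_features: int = 10,
    n_perm: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """PERMANOVA p-values under a true null (two arbitrary labels on
    homogeneous lognormal data); used to check type-I error calibration."""
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    labels = np.array(["a"] * half + ["b"] * (n_samples - half))
    pvals = np.empty(n_sims)
    for i in range(n_sims):
        x = pd.DataFrame(
            rng.lognormal(0.0, 1.0, (n_samples, n_features)),
            index=[f"s{j}" for j in range(n_samples)],
        )
        d = bray_curtis(x)
        _, pvals[i] = permanova(
            d, labels, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
        )
    return pvals


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, p two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Welch's t-test needs n >= 2 per sample")
    res = stats.ttest_ind(a, b, equal_var=False)
    if math.isnan(res.statistic):
        # both samples constant and equal: no evidence of difference
        return 0.0, float(len(a) + len(b) - 2), 1.0
    return float(res.statistic), float(res.df), float(res.pvalue)


def ward_order(median_abund: pd.DataFrame) -> list[str]:
    """Leaf order of Ward clustering on Euclidean distances between rows.

    Rows are pre-sorted lexicographically by label so that distance ties are
    broken deterministically.
    """
    if len(median_abund) < 2:
        return [str(i) for i in median_abund.index]
    ordered = median_abund.sort_index(key=lambda idx: idx.astype(str))
    z = hierarchy.linkage(ordered.to_numpy(dtype=float), method="ward")
    leaves = hierarchy.leaves_list(z)
    return [str(ordered.index[i]) for i in leaves]
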