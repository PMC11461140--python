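"""Simulation-null phylogenetic ANOVA and MANOVA.

Group comparisons of species traits (or PC scores) cannot use the classical
F or Wilks null distributions because species are phylogenetically
correlated.  Instead, the observed statistic is compared against statistics
recomputed on ``nsim`` Brownian-motion datasets simulated along the tree,
with the evolutionary rate (or rate matrix) estimated from the observed
data and the group assignment held fixed.  The p-value uses the plus-one
rule, p = (1 + #{simulated at least as extreme}) / (nsim + 1), so it is
never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, vcv
from .ppca import phylo_mean

__all__ = ["PhyloAnovaResult", "anova_f", "wilks_lambda", "phyl_anova", "phyl_manova"]


@dataclass
class PhyloAnovaResult:
    statistic: float
    statistic_kind: str  # "F" or "wilks"
    nsim: int
    p_sim: float
    seed: int
    group_sizes: dict[str, int]


def _group_index(groups):
    groups = np.asarray(groups)
    labels, g = np.unique(groups, return_inverse=True)
    return labels, g


def _validate_groups(n_obs: int, labels, counts):
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts == 0):
        raise ValueError("every group needs at least one member")
    if n_obs <= len(labels):
        raise ValueError("total n must exceed the number of groups")


def anova_f(y, groups) -> float:
    """Classical one-way ANOVA F statistic (between-group MS / within-group MS)."""
    y = np.asarray(y, dtype=float)
    labels, g = _group_index(groups)
    k = len(labels)
    counts = np.bincount(g, minlength=k)
    _validate_groups(y.size, labels, counts)
    grand = y.mean()
    means = np.bincount(g, weights=y, minlength=k) / counts
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[g]) ** 2))
    if ssw == 0.0 and ssb == 0.0:
        raise ValueError("zero variance within and between groups; F undefined")
    msb = ssb / (k - 1)
    msw = ssw / (y.size - k)
    return np.inf if msw == 0.0 else msb / msw


def _anova_f_rows(Y: np.ndarray, g: np.ndarray, k: int, counts: np.ndarray) -> np.ndarray:
    """Vectorised F statistic for each row of Y (rows = simulated datasets)."""
    n = Y.shape[1]
    G = np.zeros((n, k))
    G[np.arange(n), g] = 1.0
    means = (Y @ G) / counts
    grand = Y.mean(axis=1, keepdims=True)
    ssb = np.sum(counts * (means - grand) ** 2, axis=1)
    sst = np.sum((Y - grand) ** 2, axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    return F


def wilks_lambda(Y, groups) -> float:
    """Wilks' lambda: det(W) / det(W + B) of within/between cross-products."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    labels, g = _group_index(groups)
    k = len(labels)
    counts = np.bincount(g, minlength=k)
    _validate_groups(n, labels, counts)
    if n <= p + k:
        raise ValueError(f"need n > p + #groups (n={n}, p={p}, groups={k})")
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for j in range(k):
        Yj = Y[g == j]
        mj = Yj.mean(axis=0)
        dj = Yj - mj
        W += dj.T @ dj
        B += counts[j] * np.outer(mj - grand, mj - grand)
    T = W + B
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0:
        raise np.linalg.LinAlgError("total cross-product matrix is singular")
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def _bm_rate(y: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """REML Brownian rate and phylogenetic mean of a single trait on C."""
    a = float(phylo_mean(y[:, None], C)[0])
    r = y - a
    sigma2 = float(r @ np.linalg.solve(C, r)) / (y.size - 1)
    return a, sigma2


def _check_alignment(values, groups, tree: Phylogeny):
    if isinstance(values, (pd.Series, pd.DataFrame)):
        values = values.loc[list(tree.tip_labels)]
    if isinstance(groups, (pd.Series, dict)):
        groups = pd.Series(groups).loc[list(tree.tip_labels)].to_numpy()
    arr = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if arr.shape[0] != tree.n_tips or groups.shape[0] != tree.n_tips:
        raise ValueError("values/groups do not map onto the tree tips")
    return arr, groups


def phyl_anova(y, groups, tree: Phylogeny, nsim: int = 1000, seed: int = 0) -> PhyloAnovaResult:
    """Phylogenetic one-way ANOVA with a Brownian simulation null.

    The observed F is classical; the null distribution simulates ``nsim``
    Brownian datasets on the tree at the REML rate estimated from ``y``
    (group labels fixed).  Deterministic given ``seed``.
    """
    if nsim < 100:
        warnings.warn(f"nsim={nsim} is small; p-value resolution is coarse", stacklevel=2)
    y, groups = _check_alignment(y, groups, tree)
    y = y.reshape(-1)
    labels, g = _group_index(groups)
    k = len(labels)
    counts = np.bincount(g, minlength=k).astype(float)
    _validate_groups(y.size, labels, counts)
    F_obs = anova_f(y, groups)

    C = vcv(tree).values
    _, sigma2 = _bm_rate(y, C)
    L = np.linalg.cholesky(sigma2 * C)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((tree.n_tips, nsim))
    Ysim = (L @ Z).T
    F_sim = _anova_f_rows(Ysim, g, k, counts)
    p = (1.0 + float(np.sum(F_sim >= F_obs))) / (nsim + 1.0)
    return PhyloAnovaResult(
        statistic=float(F_obs),
        statistic_kind="F",
        nsim=nsim,
        p_sim=p,
        seed=seed,
        group_sizes={str(lab): int(c) for lab, c in zip(labels, counts)},
    )


def phyl_manova(Y, groups, tree: Phylogeny, nsim: int = 1000, seed: int = 0) -> PhyloAnovaResult:
    """Phylogenetic MANOVA (Wilks' lambda) with a multivariate Brownian null.

    The trait rate matrix is the evolutionary covariance estimated from the
    observed data on the untransformed (lambda = 1) tree; smaller Wilks'
    lambda is more extreme.
    """
    if nsim < 100:
        warnings.warn(f"nsim={nsim} is small; p-value resolution is coarse", stacklevel=2)
    Y, groups = _check_alignment(Y, groups, tree)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    labels, g = _group_index(groups)
    k = len(labels)
    counts = np.bincount(g, minlength=k)
    _validate_groups(n, labels, counts)
    lam_obs = wilks_lambda(Y, groups)

    C = vcv(tree).values
    a = phylo_mean(Y, C)
    Yc = Y - a
    R = Yc.T @ np.linalg.solve(C, Yc) / (n - 1)
    Lc = np.linalg.cholesky(C)
    Lr = np.linalg.cholesky(R + 1e-12 * np.eye(p) * np.trace(R))
    rng = np.random.default_rng(seed)
    count_extreme = 0
    for _ in range(nsim):
        Z = rng.standard_normal((n, p))
        Ysim = Lc @ Z @ Lr.T
        if wilks_lambda(Ysim, groups) <= lam_obs:
            count_extreme += 1
    p_sim = (1.0 + count_extreme) / (nsim + 1.0)
    return PhyloAnovaResult(
        statistic=float(lam_obs),
        statistic_kind="wilks",
        nsim=nsim,
        p_sim=p_sim,
        seed=seed,
        group_sizes={str(lab): int(c) for lab, c in zip(labels, counts)},
    )
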