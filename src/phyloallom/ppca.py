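"""Phylogenetic principal component analysis (lambda method, correlation mode).

Ordinary PCA of species traits conflates within-lineage variation with
shared ancestry.  The phylogenetic variant eigendecomposes the
*evolutionary* correlation matrix

    R = (X - 1 a')' C(lambda)^-1 (X - 1 a') / (n - 1),   standardised,

where a is the GLS (phylogenetic) mean vector and C(lambda) the Pagel-
transformed VCV, with lambda estimated by maximising the multivariate
Brownian likelihood.  Scores are the centred raw data (standardised by the
GLS variances in correlation mode) projected on the eigenvectors — not
whitened by C^-1 — matching the output convention of the field's reference
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .phylo import Phylogeny, VCVMatrix, vcv

__all__ = [
    "PPCAResult",
    "phylo_mean",
    "evol_covariance",
    "fit_lambda_mv",
    "ppca",
    "kaiser_guttman",
    "variance_explained",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PPCAResult:
    lam: float
    phylo_means: np.ndarray
    evol_correlation: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray  # columns = components
    scores: np.ndarray  # n x p, rows follow `taxa`
    retained: int
    taxa: tuple[str, ...]
    traits: tuple[str, ...]
    mode: str = "corr"
    lambda_flag: str = ""

    def explained(self) -> np.ndarray:
        return variance_explained(self.eigenvalues)


def _as_matrix(X, tree: Phylogeny | None):
    if isinstance(X, pd.DataFrame):
        traits = tuple(map(str, X.columns))
        if tree is not None:
            X = X.loc[list(tree.tip_labels)]
        taxa = tuple(map(str, X.index))
        return X.to_numpy(dtype=float), taxa, traits
    X = np.asarray(X, dtype=float)
    taxa = tree.tip_labels if tree is not None else tuple(f"t{i}" for i in range(X.shape[0]))
    traits = tuple(f"trait{j}" for j in range(X.shape[1]))
    return X, taxa, traits


def phylo_mean(X, C: VCVMatrix | np.ndarray) -> np.ndarray:
    """GLS estimate of the ancestral (phylogenetic) mean of each column."""
    Xm = np.asarray(X, dtype=float)
    Cm = C.values if isinstance(C, VCVMatrix) else np.asarray(C, dtype=float)
    one = np.ones(Cm.shape[0])
    Ci_one = np.linalg.solve(Cm, one)
    denom = one @ Ci_one
    return (Ci_one @ Xm) / denom


def evol_covariance(X, C: VCVMatrix | np.ndarray, lam: float = 1.0, mode: str = "cov"):
    """Evolutionary covariance (or correlation) of traits under BM-with-lambda."""
    Xm = np.asarray(X, dtype=float)
    Cm = C.values if isinstance(C, VCVMatrix) else np.asarray(C, dtype=float)
    Clam = lam * Cm + (1.0 - lam) * np.diag(np.diag(Cm))
    n = Xm.shape[0]
    a = phylo_mean(Xm, Clam)
    Xc = Xm - a
    R = Xc.T @ np.linalg.solve(Clam, Xc) / (n - 1)
    if mode == "corr":
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return R


class _MVProfile:
    """Eigendecomposition cache for the multivariate Brownian lambda profile."""

    def __init__(self, X: np.ndarray, C: np.ndarray):
        self.X = X
        self.n, self.p = X.shape
        d = np.diag(C).copy()
        sq = np.sqrt(d)
        Cstar = C / np.outer(sq, sq)
        s, U = np.linalg.eigh(0.5 * (Cstar + Cstar.T))
        self.s, self.sq = s, sq
        self.logdet_D = float(np.sum(np.log(d)))
        self.Xt = U.T @ (X / sq[:, None])
        self.onet = U.T @ (1.0 / sq)
        smin = float(s.min())
        self.pd_hi = 1.0 / (1.0 - smin) if smin < 1.0 - 1e-12 else np.inf
        self.identifiable = (float(s.max()) - smin) > 1e-10

    def _moments(self, lam: float):
        w = 1.0 + lam * (self.s - 1.0)
        if np.min(w) <= 1e-12:
            return None
        ow = self.onet / w
        denom = float(self.onet @ ow)
        a = (ow @ self.Xt) / denom
        Xc = self.Xt - np.outer(self.onet, a)
        S = Xc.T @ (Xc / w[:, None])
        logdet_C = self.logdet_D + float(np.sum(np.log(w)))
        return a, S, logdet_C

    def loglik(self, lam: float) -> float:
        out = self._moments(lam)
        if out is None:
            return -1e300
        _, S, logdet_C = out
        n, p = self.n, self.p
        R_ml = S / n
        sign, logdet_R = np.linalg.slogdet(R_ml)
        if sign <= 0:
            return -1e300
        return -0.5 * (n * logdet_R + p * logdet_C + n * p * (_LOG_2PI + 1.0))


def fit_lambda_mv(X, tree: Phylogeny, upper: float = 1.0, n_grid: int = 51):
    """ML estimate of lambda for multivariate Brownian data on a tree.

    Constrained to [0, min(upper, lambda_max)] where lambda_max keeps
    C(lambda) positive definite.  Returns (lambda_hat, flag) with flag
    "unidentifiable" on a star tree and "boundary" on a boundary optimum.
    """
    Xm, _, _ = _as_matrix(X, tree)
    if Xm.shape[0] <= Xm.shape[1]:
        raise ValueError("need more species than traits")
    C = vcv(tree).values
    prof = _MVProfile(Xm, C)
    if not prof.identifiable:
        return 0.0, "unidentifiable"
    hi = min(upper, prof.pd_hi * (1 - 1e-8))
    grid = np.linspace(0.0, hi, n_grid)
    vals = np.array([prof.loglik(g) for g in grid])
    ibest = int(np.argmax(vals))
    a = grid[max(ibest - 1, 0)]
    b = grid[min(ibest + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda t: -prof.loglik(t), bounds=(a, b), method="bounded", options={"xatol": 1e-8}
    )
    lam = float(res.x)
    flag = "boundary" if (lam < 1e-6 or hi - lam < 1e-6) else ""
    return lam, flag


def ppca(X, tree: Phylogeny, mode: str = "corr", prestandardise: bool = False) -> PPCAResult:
    """Phylogenetic PCA with lambda estimated from the data.

    ``X`` is a complete-case species x trait matrix (DataFrame rows are
    aligned to the tree's tips by label).  In 'corr' mode the evolutionary
    covariance is standardised to a correlation matrix and scores use
    GLS-variance-standardised centred data.  Eigenvector signs follow the
    convention that each component's largest-magnitude loading is positive.
    """
    Xm, taxa, trait_names = _as_matrix(X, tree)
    if np.isnan(Xm).any():
        raise ValueError(
            "missing values in trait matrix; assemble complete cases before calling ppca"
        )
    n, p = Xm.shape
    if n <= p:
        raise ValueError(f"need more species than traits (n={n}, p={p})")
    if mode not in ("corr", "cov"):
        raise ValueError(f"mode must be 'corr' or 'cov', got {mode!r}")
    if prestandardise:
        Xm = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0, ddof=1)

    lam, flag = fit_lambda_mv(pd.DataFrame(Xm, index=list(taxa)), tree)
    C = vcv(tree).values
    Clam = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    a = phylo_mean(Xm, Clam)
    Xc = Xm - a
    R = Xc.T @ np.linalg.solve(Clam, Xc) / (n - 1)
    gls_sd = np.sqrt(np.diag(R))
    if mode == "corr":
        Rm = R / np.outer(gls_sd, gls_sd)
        np.fill_diagonal(Rm, 1.0)
        Xs = Xc / gls_sd
    else:
        Rm = R
        Xs = Xc

    evals, evecs = np.linalg.eigh(Rm)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(p):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xs @ evecs
    return PPCAResult(
        lam=lam,
        phylo_means=a,
        evol_correlation=Rm,
        eigenvalues=evals,
        loadings=evecs,
        scores=scores,
        retained=kaiser_guttman(evals),
        taxa=taxa,
        traits=trait_names,
        mode=mode,
        lambda_flag=flag,
    )


def kaiser_guttman(eigenvalues) -> int:
    """Number of eigenvalues strictly greater than the mean eigenvalue."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(ev < -1e-10):
        raise ValueError("negative eigenvalue")
    return int(np.sum(ev > ev.mean()))


def variance_explained(eigenvalues) -> np.ndarray:
    """Fraction of total variance per component: eigenvalue / sum."""
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        raise ValueError("eigenvalues sum to zero")
    return ev / total
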