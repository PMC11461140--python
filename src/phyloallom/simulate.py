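"""Synthetic trees and trait datasets with the statistical structure the
pipeline assumes.

The generators emulate a large comparative life-history study: a pure-birth
(Yule) phylogeny of ~2000 species, log10 body mass evolving by Brownian
motion, per-trait log-log allometries with phylogenetically correlated
residuals (Pagel's lambda mostly between 0.5 and 1), per-trait missingness
reproducing the wildly uneven literature coverage (n from ~2000 down to
~15), and a five-trait "fast-slow" dataset driven by two latent
phylogenetic factors — a pace-of-life factor loading positively on every
trait and a trade-off factor with opposite signs on egg volume and clutch
size.  Everything is bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny, vcv

__all__ = [
    "TraitAllometry",
    "StudyConfig",
    "FastSlowConfig",
    "default_study_config",
    "default_fastslow_config",
    "yule_tree",
    "simulate_bm",
    "simulate_allometric_study",
    "make_fastslow",
    "FASTSLOW_TRAITS",
]


def yule_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth tree with ``n_taxa`` extant tips.

    Lineages split at exponential waiting times (rate = k * birth_rate with
    k current lineages); after the last split one further waiting time is
    drawn so terminal branches have positive length.  All tips end at the
    present, so the tree is ultrametric.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)

    parent: list[int] = []
    blen: list[float] = []
    start_time: list[float] = []

    def new_node(par: int, t0: float) -> int:
        parent.append(par)
        blen.append(0.0)
        start_time.append(t0)
        return len(parent) - 1

    root = new_node(-1, 0.0)
    active = [new_node(root, 0.0), new_node(root, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        blen[node] = t - start_time[node]
        active.append(new_node(node, t))
        active.append(new_node(node, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        blen[node] = t - start_time[node]

    # renumber: tips first (in active order), then internals
    tips = active
    tipset = set(tips)
    internals = [i for i in range(len(parent)) if i not in tipset]
    remap = {old: new for new, old in enumerate(tips + internals)}
    n_nodes = len(parent)
    new_parent = np.empty(n_nodes, dtype=np.int64)
    new_blen = np.empty(n_nodes)
    for old in range(n_nodes):
        new = remap[old]
        new_parent[new] = remap[parent[old]] if parent[old] >= 0 else -1
        new_blen[new] = blen[old]
    labels = tuple(f"t{i + 1}" for i in range(len(tips)))
    return Phylogeny(labels, new_parent, new_blen)


class _LambdaSampler:
    """Draws N(0, C(lambda)) vectors for many lambdas from one eigendecomposition."""

    def __init__(self, tree: Phylogeny):
        C = vcv(tree).values
        d = np.diag(C).copy()
        self.sq = np.sqrt(d)
        Cstar = C / np.outer(self.sq, self.sq)
        s, U = np.linalg.eigh(0.5 * (Cstar + Cstar.T))
        self.s, self.U = np.clip(s, 0.0, None), U
        self.depth = d

    def draw(self, lam: float, rng: np.random.Generator, ncol: int = 1) -> np.ndarray:
        w = 1.0 + lam * (self.s - 1.0)
        if np.min(w) < 0:
            raise ValueError(f"lambda={lam} gives a non-PSD covariance on this tree")
        Z = rng.standard_normal((self.s.size, ncol))
        out = self.sq[:, None] * (self.U @ (np.sqrt(w)[:, None] * Z))
        return out[:, 0] if ncol == 1 else out


def simulate_bm(
    tree: Phylogeny,
    lambda_true: float,
    R: np.ndarray,
    root: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """One multivariate Brownian draw on the tree (log scale).

    Trait covariance between tips follows R (kron) C(lambda_true); rows are
    tips in tree order, columns traits.  ``root`` gives the ancestral mean
    of each trait.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    root = np.atleast_1d(np.asarray(root, dtype=float))
    p = R.shape[0]
    if R.shape != (p, p) or root.shape != (p,):
        raise ValueError("R must be p x p and root length p")
    try:
        Lr = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rate matrix R must be positive definite") from exc
    rng = np.random.default_rng(seed)
    sampler = _LambdaSampler(tree)
    Z = sampler.draw(lambda_true, rng, ncol=p)  # each column ~ N(0, C(lambda))
    Z = Z.reshape(tree.n_tips, p)
    X = root + Z @ Lr.T
    return pd.DataFrame(X, index=list(tree.tip_labels), columns=[f"trait{j}" for j in range(p)])


@dataclass(frozen=True)
class TraitAllometry:
    """Generating parameters of one trait: log10(TR) = intercept + slope*log10(M) + eps."""

    name: str
    slope: float
    intercept: float
    resid_sd: float
    lam: float
    retention: float  # fraction of species with a value for this trait
    category: str | None = None

    def __post_init__(self):
        if self.resid_sd <= 0:
            raise ValueError(f"{self.name}: residual sd must be positive")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError(f"{self.name}: retention must be in (0, 1]")


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the emulated allometric study."""

    n_taxa: int = 2069
    birth_rate: float = 1.0
    mass_root_log10: float = 1.0  # 10 g ancestral adult mass
    mass_sd_log10: float = 0.7  # tip sd of log10 mass (~3 orders of magnitude range)
    traits: tuple[TraitAllometry, ...] = ()
    block_missingness: bool = False  # clade-biased instead of completely-at-random


def default_study_config(n_taxa: int = 2069) -> StudyConfig:
    """Defaults mirroring the study's structure: 16 traits, slopes/lambdas of
    the all-amphibian allometric table, per-trait n from its sample sizes."""
    N = 2069  # species count the retention fractions are quoted against

    def t(name, slope, intercept, lam, n, category=None, sd=0.25):
        return TraitAllometry(name, slope, intercept, sd, lam, min(n / N, 1.0), category)

    traits = (
        t("egg_volume", 0.18, -1.99, 0.92, 1362),
        t("egg_diameter", 0.06, 0.43, 0.92, 1362),
        t("clutch_size", 0.45, 1.22, 0.90, 1860),
        t("clutch_volume", 0.71, -0.78, 0.49, 1240, "biomass_product"),
        t("annual_clutch_number", 0.01, 0.05, 0.94, 35, "biological_rate"),
        t("annual_clutch_volume", 0.12, 0.63, 1.00, 33, "production_rate"),
        t("incubation_time", -0.03, 1.56, 0.91, 191, "biological_time"),
        t("hatchling_total_length", 0.10, 1.19, 0.99, 105),
        t("hatchling_svl", 0.02, 0.73, 1.00, 42),
        t("larval_period", 0.07, 1.99, 0.93, 167, "biological_time"),
        t("metamorphosis_total_length", 0.14, 1.43, 0.82, 204),
        t("metamorphosis_svl", 0.17, 1.11, 0.84, 65),
        t("juvenile_mass", 0.55, -0.70, 0.62, 22, "biomass_product"),
        t("size_at_maturity", 0.21, 1.68, 0.74, 237),
        t("age_at_maturity", 0.11, 0.26, 0.84, 418, "biological_time"),
        t("max_longevity", 0.14, 0.81, 0.55, 524, "biological_time"),
    )
    return StudyConfig(n_taxa=n_taxa, traits=traits)


def simulate_allometric_study(
    config: StudyConfig, tree: Phylogeny | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate the full study trait table (natural units, NaN = missing).

    log10 body mass evolves by Brownian motion; each trait is its allometric
    prediction plus a BM-with-lambda residual scaled to the stated tip sd;
    missingness is Bernoulli per trait (or clade-blocked when configured).
    Column ``body_mass`` is complete; all values are back-transformed to
    natural units.
    """
    if not config.traits:
        raise ValueError("config has no traits")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = yule_tree(config.n_taxa, config.birth_rate, seed=int(rng.integers(2**31)))
    sampler = _LambdaSampler(tree)
    depth = float(np.max(sampler.depth))

    mass_log = config.mass_root_log10 + config.mass_sd_log10 * sampler.draw(1.0, rng) / np.sqrt(
        depth
    )
    data = {"body_mass": 10.0**mass_log}
    n = tree.n_tips
    order = np.arange(n)
    for tr in config.traits:
        resid = tr.resid_sd * sampler.draw(tr.lam, rng) / np.sqrt(depth)
        y_log = tr.intercept + tr.slope * mass_log + resid
        y = 10.0**y_log
        if tr.retention < 1.0:
            if config.block_missingness:
                # retain one contiguous block of the tip order (clade-biased sample)
                m = max(3, int(round(tr.retention * n)))
                start = int(rng.integers(0, n - m + 1))
                mask = np.zeros(n, dtype=bool)
                mask[order[start : start + m]] = True
            else:
                mask = rng.random(n) < tr.retention
            y = np.where(mask, y, np.nan)
        data[tr.name] = y
    return pd.DataFrame(data, index=list(tree.tip_labels))


FASTSLOW_TRAITS = ("body_mass", "egg_volume", "clutch_size", "age_at_maturity", "max_longevity")


@dataclass(frozen=True)
class FastSlowConfig:
    """Two-factor generating model of the five fast-slow traits (log scale).

    ``pace_loadings`` load every trait on a shared pace-of-life factor;
    ``tradeoff_loadings`` oppose egg volume and clutch size.  Both factors
    evolve as Brownian motion with the stated phylogenetic signal.
    """

    n_taxa: int = 263
    birth_rate: float = 1.0
    lambda_true: float = 0.8
    means: tuple[float, ...] = (1.0, -2.0, 2.3, 0.3, 1.0)  # log10 natural-unit scales
    pace_loadings: tuple[float, ...] = (0.9, 0.45, 0.45, 0.7, 0.7)
    tradeoff_loadings: tuple[float, ...] = (0.0, 0.6, -0.6, 0.0, 0.0)
    noise_sd: float = 0.25

    def __post_init__(self):
        for name in ("means", "pace_loadings", "tradeoff_loadings"):
            if len(getattr(self, name)) != len(FASTSLOW_TRAITS):
                raise ValueError(f"{name} must have {len(FASTSLOW_TRAITS)} entries")
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")


def default_fastslow_config(**overrides) -> FastSlowConfig:
    return FastSlowConfig(**overrides)


def make_fastslow(
    config: FastSlowConfig | None = None, tree: Phylogeny | None = None, seed: int = 0
) -> pd.DataFrame:
    """Five-trait dataset with a pace factor and an egg/clutch trade-off factor.

    Returns natural-unit values (no missingness) for body mass, egg volume,
    clutch size, age at maturity and maximum longevity.
    """
    config = config or FastSlowConfig()
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = yule_tree(config.n_taxa, config.birth_rate, seed=int(rng.integers(2**31)))
    sampler = _LambdaSampler(tree)
    depth = float(np.max(sampler.depth))
    factors = sampler.draw(config.lambda_true, rng, ncol=2) / np.sqrt(depth)
    lp = np.asarray(config.pace_loadings)
    lt = np.asarray(config.tradeoff_loadings)
    mu = np.asarray(config.means)
    n = tree.n_tips
    noise = config.noise_sd * rng.standard_normal((n, len(FASTSLOW_TRAITS)))
    X_log = mu + np.outer(factors[:, 0], lp) + np.outer(factors[:, 1], lt) + noise
    return pd.DataFrame(10.0**X_log, index=list(tree.tip_labels), columns=list(FASTSLOW_TRAITS))
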