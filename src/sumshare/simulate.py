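"""Synthetic multi-site data generator.

Emulates the evaluation conditions for the distributed pleiotropy test:
a single biallelic SNP drawn under Hardy-Weinberg equilibrium, ``q`` binary
phenotypes from marginal logistic models

    logit P(Y_j = 1 | X) = beta0 + X * beta_j  [+ gender*gamma + age*delta],

optional cross-phenotype correlation through a Gaussian copula, and
optional gender/age covariates.  Effects are homogeneous across sites;
sites differ only in sample size and, when requested, allele frequency.

Default study conditions: ten sites of n=100 patients, q=10 phenotypes,
intercept -0.5 (≈40% baseline prevalence), MAF 0.05.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .errors import ValidationError
from .types import SimulationScenario, SiteDataset

__all__ = [
    "simulate_genotypes",
    "beta_pattern",
    "simulate_phenotypes",
    "simulate_phenotypes_correlated",
    "simulate_covariates",
    "block_correlation",
    "simulate_multisite",
    "discretize_age",
]

PATTERNS = ("same", "opposite", "sparse", "null")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, maf: float, seed=None) -> np.ndarray:
    """Draw ``n`` additive genotype codes under Hardy-Weinberg equilibrium.

    Genotypes 0/1/2 occur with probabilities ``((1-p)^2, 2p(1-p), p^2)``
    for minor-allele frequency ``p``.
    """
    if not 0.0 <= maf <= 0.5:
        raise ValidationError(f"maf must lie in [0, 0.5]; got {maf}")
    p = float(maf)
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    return _rng(seed).choice(3, size=int(n), p=probs).astype(float)


def beta_pattern(
    pattern: str, q: int, beta_ref: float, *, sparse_from_one: bool = False
) -> np.ndarray:
    """Effect-size vector for one of the pleiotropy patterns.

    same
        All q effects equal ``beta_ref``.
    opposite
        First ``ceil(q/2)`` effects ``+beta_ref``, the rest ``-beta_ref``.
    sparse
        Geometrically decaying ``2^-i * beta_ref`` for i = 1..q, so the
        leading phenotype carries ``beta_ref/2``; ``sparse_from_one=True``
        starts the decay at ``beta_ref`` itself (``2^-(i-1)``).
    null
        All zeros.
    """
    if q < 1:
        raise ValidationError("q must be >= 1")
    if pattern == "same":
        return np.full(q, beta_ref)
    if pattern == "opposite":
        half = -(-q // 2)
        return np.concatenate([np.full(half, beta_ref), np.full(q - half, -beta_ref)])
    if pattern == "sparse":
        start = 0 if sparse_from_one else 1
        return beta_ref * 2.0 ** -(np.arange(start, start + q, dtype=float))
    if pattern == "null":
        return np.zeros(q)
    raise ValidationError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")


def _success_probs(
    x: np.ndarray,
    beta: np.ndarray,
    beta0: float,
    gender: np.ndarray | None = None,
    age: np.ndarray | None = None,
    gamma: float = 0.0,
    delta: float = 0.0,
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float).ravel()
    eta = beta0 + np.outer(x, beta)
    if gender is not None:
        eta += gamma * np.asarray(gender, dtype=float)[:, None]
    if age is not None:
        eta += delta * np.asarray(age, dtype=float)[:, None]
    return expit(eta)


def simulate_phenotypes(
    x: np.ndarray,
    beta: np.ndarray,
    beta0: float = -0.5,
    gender: np.ndarray | None = None,
    age: np.ndarray | None = None,
    gamma: float = 0.0,
    delta: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Independent binary phenotypes from the marginal logistic model.

    Each cell is Bernoulli with success probability
    ``expit(beta0 + x*beta_j + gender*gamma + age*delta)``.
    """
    P = _success_probs(x, beta, beta0, gender, age, gamma, delta)
    return (_rng(seed).random(P.shape) < P).astype(float)


def simulate_phenotypes_correlated(
    x: np.ndarray,
    beta: np.ndarray,
    beta0: float = -0.5,
    R: np.ndarray | None = None,
    gender: np.ndarray | None = None,
    age: np.ndarray | None = None,
    gamma: float = 0.0,
    delta: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Correlated binary phenotypes via a Gaussian copula.

    A latent vector ``z ~ N(0, R)`` is drawn per subject and thresholded:
    ``Y_j = 1`` iff ``Phi(z_j) < expit(beta0 + x*beta_j + ...)``.  Marginal
    success probabilities therefore match :func:`simulate_phenotypes`
    exactly for any correlation matrix; realised binary-scale correlations
    are attenuated relative to the latent ``R``.
    """
    P = _success_probs(x, beta, beta0, gender, age, gamma, delta)
    q = P.shape[1]
    if R is None:
        R = np.eye(q)
    R = np.asarray(R, dtype=float)
    if R.shape != (q, q):
        raise ValidationError(f"R must be {q}x{q}; got {R.shape}")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValidationError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValidationError("R must have unit diagonal")
    # cholesky doubles as the PSD check
    try:
        L = np.linalg.cholesky(R + 1e-12 * np.eye(q))
    except np.linalg.LinAlgError:
        raise ValidationError("R is not positive semi-definite") from None
    z = _rng(seed).standard_normal(P.shape) @ L.T
    return (norm.cdf(z) < P).astype(float)


def discretize_age(age: np.ndarray) -> np.ndarray:
    """Map continuous age to privacy-preserving bins: <50 -> 0, [50,75) -> 1, >=75 -> 2."""
    age = np.asarray(age, dtype=float)
    return np.where(age < 50, 0, np.where(age < 75, 1, 2)).astype(int)


def simulate_covariates(n: int, seed=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw gender ~ Bernoulli(0.5) and age ~ Normal(65, 20), plus age bins."""
    rng = _rng(seed)
    gender = (rng.random(int(n)) < 0.5).astype(int)
    age = rng.normal(65.0, 20.0, size=int(n))
    return gender, age, discretize_age(age)


def block_correlation(q: int, rho: float = 0.5, n_blocks: int = 2) -> np.ndarray:
    """Correlation matrix with equal-sized blocks of within-block correlation ``rho``.

    Phenotypes inside a block share latent correlation ``rho``; phenotypes
    in different blocks are uncorrelated.  The default (two blocks, 0.5)
    gives two correlated disease clusters.
    """
    if not 0.0 <= rho < 1.0:
        raise ValidationError(f"rho must lie in [0, 1); got {rho}")
    sizes = [q // n_blocks + (1 if b < q % n_blocks else 0) for b in range(n_blocks)]
    R = np.zeros((q, q))
    start = 0
    for s in sizes:
        R[start : start + s, start : start + s] = rho
        start += s
    np.fill_diagonal(R, 1.0)
    return R


def simulate_multisite(scenario: SimulationScenario) -> list[SiteDataset]:
    """Generate one multi-site dataset for a scenario.

    Each site draws its own genotypes (site-specific MAF allowed) and
    phenotypes from the same effect vector; with covariates enabled, gender
    and continuous age enter the generating model while the returned strata
    cross gender with the discretized age bin, mirroring how a categorical
    adjustment would be applied downstream.  Reproducible: the scenario seed
    spawns one independent substream per site.
    """
    beta = beta_pattern(
        scenario.pattern,
        scenario.q,
        scenario.beta_ref,
        sparse_from_one=scenario.sparse_from_one,
    )
    sizes = scenario.site_sizes()
    mafs = scenario.site_mafs()
    seed = scenario.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(scenario.K)
    sites: list[SiteDataset] = []
    for k, (n_k, maf_k, child) in enumerate(zip(sizes, mafs, children)):
        rng = np.random.default_rng(child)
        x = simulate_genotypes(n_k, maf_k, rng)
        gender = age = None
        strata = None
        gamma = delta = 0.0
        if scenario.with_covariates:
            gender, age, age_bin = simulate_covariates(n_k, rng)
            gamma, delta = scenario.gamma, scenario.delta
            labels = np.array(
                [f"g{g}|a{a}" for g, a in zip(gender, age_bin)], dtype=object
            )
            strata = labels
        if scenario.correlation is not None:
            y = simulate_phenotypes_correlated(
                x, beta, scenario.beta0, scenario.correlation,
                gender, age, gamma, delta, rng,
            )
        else:
            y = simulate_phenotypes(
                x, beta, scenario.beta0, gender, age, gamma, delta, rng
            )
        sites.append(
            SiteDataset(
                site_id=f"site{k + 1}", genotype=x, phenotypes=y, strata=strata
            )
        )
    return sites


def scenario_with_seed(scenario: SimulationScenario, seed) -> SimulationScenario:
    """Copy of a scenario with its seed replaced (used for per-repetition substreams)."""
    return replace(scenario, seed=seed)
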