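"""PheWAS comparator: one logistic regression per phenotype.

The phenome-wide baseline tests the SNP against each phenotype separately
with maximum-likelihood logistic regression, Bonferroni-adjusts the q Wald
p-values, and declares pleiotropy when the minimum adjusted p-value falls
below alpha.  Multi-site integration is done either by mega-analysis
(pool individual-level rows, fit once) or meta-analysis (fit per site,
combine log-odds ratios by inverse-variance weighting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core import concatenate_sites
from .errors import DegenerateDataError, ValidationError
from .types import SiteDataset

__all__ = [
    "AssociationFit",
    "PhewasDecision",
    "logistic_fit",
    "phewas_decision",
    "ivw_meta",
    "phewas_single",
    "phewas_meta",
    "phewas_mega",
]

# a Wald SE this large signals (quasi-)separation rather than information
_SE_DIVERGED = 100.0


@dataclass
class AssociationFit:
    """One SNP-phenotype logistic association."""

    phenotype: str
    beta: float
    se: float
    p: float
    converged: bool
    message: str = ""


@dataclass
class PhewasDecision:
    """Bonferroni min-p decision across the phenome."""

    phenotypes: list[str]
    p_values: np.ndarray
    adjusted_p: np.ndarray
    min_adjusted_p: float
    alpha: float
    significant: bool
    fits: list[AssociationFit] = field(default_factory=list)


def _design(
    x: np.ndarray, covariates: pd.DataFrame | np.ndarray | None
) -> tuple[np.ndarray, int]:
    """Design matrix [1, x, covariate dummies]; returns it plus the genotype index."""
    cols = [np.ones_like(x, dtype=float), np.asarray(x, dtype=float)]
    if covariates is not None:
        cov = pd.DataFrame(covariates).astype("category")
        dummies = pd.get_dummies(cov, drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
    return np.column_stack(cols), 1


def logistic_fit(
    y: np.ndarray,
    design: np.ndarray,
    term: int = 1,
    phenotype: str = "",
) -> AssociationFit:
    """Maximum-likelihood logistic fit; Wald beta/se/p for column ``term``.

    Raises :class:`DegenerateDataError` for a constant outcome or a constant
    non-intercept predictor.  Separation or non-convergence is reported via
    ``converged=False`` rather than an exception, so small sites with rare
    alleles can be skipped in meta-analysis.
    """
    y = np.asarray(y, dtype=float).ravel()
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[0] != y.shape[0]:
        raise ValidationError("design must be 2-D with one row per subject")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError(f"degenerate outcome: phenotype {phenotype!r} is constant")
    for c in range(design.shape[1]):
        col = design[:, c]
        if c != 0 and np.ptp(col) == 0:
            raise DegenerateDataError(
                f"constant predictor: design column {c} has no variation"
            )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
        beta = float(res.params[term])
        se = float(res.bse[term])
        p = float(res.pvalues[term])
        ok = (
            bool(res.mle_retvals.get("converged", False))
            and np.isfinite(se)
            and se < _SE_DIVERGED
        )
        msg = "" if ok else "non-convergence or separation"
        return AssociationFit(phenotype, beta, se, p, ok, msg)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return AssociationFit(
            phenotype, float("nan"), float("nan"), float("nan"), False, str(exc)
        )


def phewas_decision(
    pvals: Sequence[float],
    alpha: float = 0.05,
    phenotypes: Sequence[str] | None = None,
    fits: list[AssociationFit] | None = None,
) -> PhewasDecision:
    """Bonferroni-adjust q p-values and test the minimum against alpha."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.nanmin(p) <= 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in (0, 1]")
    q = p.size
    adjusted = np.minimum(1.0, q * p)
    min_adj = float(np.nanmin(adjusted))
    names = list(phenotypes) if phenotypes is not None else [f"y{j+1}" for j in range(q)]
    return PhewasDecision(
        phenotypes=names,
        p_values=p,
        adjusted_p=adjusted,
        min_adjusted_p=min_adj,
        alpha=alpha,
        significant=min_adj < alpha,
        fits=fits or [],
    )


def ivw_meta(fits: Sequence[AssociationFit]) -> AssociationFit:
    """Fixed-effect inverse-variance-weighted combination of per-site fits.

    Weights ``w_k = 1/se_k^2``; the meta estimate is the weighted mean of
    the log-odds ratios, its standard error ``(sum w_k)^{-1/2}``, and the
    p-value is two-sided Wald against a standard normal.  Non-converged
    fits are excluded; all-non-converged raises.
    """
    usable = [f for f in fits if f.converged and np.isfinite(f.se) and f.se > 0]
    if not usable:
        raise DegenerateDataError(
            "no converged site-level fits to meta-analyze"
        )
    w = np.array([1.0 / f.se**2 for f in usable])
    betas = np.array([f.beta for f in usable])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * norm.sf(abs(z)))
    return AssociationFit(
        phenotype=usable[0].phenotype,
        beta=beta,
        se=se,
        p=max(p, np.finfo(float).tiny),
        converged=True,
        message=f"ivw over {len(usable)}/{len(fits)} sites",
    )


def _fit_all_phenotypes(
    data: SiteDataset, adjust_for_strata: bool
) -> list[AssociationFit]:
    fits = []
    for j in range(data.q):
        cov = data.strata_for(j)[:, None] if adjust_for_strata and data.strata is not None else None
        design, term = _design(data.genotype, cov)
        fits.append(
            logistic_fit(data.phenotypes[:, j], design, term, phenotype=f"y{j+1}")
        )
    return fits


def phewas_single(
    data: SiteDataset, alpha: float = 0.05, adjust_for_strata: bool = False
) -> PhewasDecision:
    """PheWAS on one dataset: per-phenotype fits, then Bonferroni min-p."""
    fits = _fit_all_phenotypes(data, adjust_for_strata)
    # non-converged fits carry no evidence: treat as p = 1
    pvals = [f.p if f.converged else 1.0 for f in fits]
    return phewas_decision(pvals, alpha, [f.phenotype for f in fits], fits)


def phewas_meta(
    sites: Sequence[SiteDataset],
    alpha: float = 0.05,
    adjust_for_strata: bool = False,
) -> PhewasDecision:
    """Meta-analysis PheWAS: fit per site, IVW per phenotype, then min-p."""
    if not sites:
        raise ValidationError("need at least one site")
    per_site = [_fit_all_phenotypes(d, adjust_for_strata) for d in sites]
    q = sites[0].q
    meta_fits = []
    for j in range(q):
        meta_fits.append(ivw_meta([fits[j] for fits in per_site]))
    pvals = [f.p for f in meta_fits]
    return phewas_decision(pvals, alpha, [f.phenotype for f in meta_fits], meta_fits)


def phewas_mega(
    sites: Sequence[SiteDataset],
    alpha: float = 0.05,
    adjust_for_strata: bool = False,
) -> PhewasDecision:
    """Mega-analysis PheWAS: pool individual-level rows, then single-site PheWAS."""
    return phewas_single(concatenate_sites(sites), alpha, adjust_for_strata)
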