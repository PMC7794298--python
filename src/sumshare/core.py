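"""The distributed pleiotropy score test.

One SNP ``X`` is tested jointly against ``q`` binary phenotypes
``Y_1..Y_q`` under marginal logistic models

    logit P(Y_j = 1 | X) = alpha_j + beta_j * X,

combined through a composite likelihood (the product of the q marginal
likelihoods, ignoring their dependence).  The null hypothesis is
``beta = 0`` for all phenotypes simultaneously.  Because the composite
likelihood misstates the joint dependence, the score statistic uses the
robust (empirical) variance of the score:

    T = S V^{-1} S',      S = sum_i u_i,    V = sum_i u_i u_i',

where the per-subject score contribution for phenotype j is the
stratum-centered cross product

    u_{ij} = (x_i - xbar_{j,s_j(i)}) * (y_{ij} - p_{j,s_j(i)}),

with ``p_{j,s}`` the pooled prevalence of phenotype j in stratum s (the
profiled-out null intercept) and ``xbar_{j,s}`` the pooled genotype mean in
that stratum.  With no covariates there is a single stratum and the sums
collapse to the textbook forms ``S_j = sum_i x_i (y_ij - ybar_j)`` and
``V_jl = sum_i (x_i - xbar)^2 (y_ij - ybar_j)(y_il - ybar_l)`` — the
genotype centering in S is immaterial there because the phenotype residuals
sum to zero over the pooled sample.  Under the null, T is asymptotically
chi-square with q degrees of freedom.

Every term of S and V is a sum over subjects, so the statistic decomposes
exactly over sites: each site ships per-stratum counts and sums (round 1),
receives pooled means, and ships its ``S_k``, ``V_k`` (round 2).  The
distributed statistic is mathematically identical to the pooled one —
lossless integration — differing only in floating-point summation order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.stats import chi2

from .errors import (
    DegenerateDataError,
    SingularVarianceError,
    ValidationError,
)
from .types import (
    PooledCell,
    PooledReference,
    SiteDataset,
    Stage1Summary,
    Stage2Summary,
    StratumCell,
    TestResult,
    UNSTRATIFIED,
)

#: Reporting floor for p-values (double-precision machine epsilon, the
#: smallest p a survival function evaluated as ``1 - CDF`` can resolve).
P_FLOOR = 2.22e-16


# ---------------------------------------------------------------------------
# round 1: per-site counts and sums -> pooled means
# ---------------------------------------------------------------------------

def site_stage1(data: SiteDataset) -> Stage1Summary:
    """Compute one site's round-1 summary: per-stratum counts and sums.

    Only aggregates leave the site: for every phenotype j and stratum s the
    cell count, the phenotype sum and the genotype sum.  Unadjusted analyses
    use a single stratum, so the message reduces to ``n_k`` and the site
    means of each phenotype and of the genotype.
    """
    x = data.genotype
    cells: list[dict[str, StratumCell]] = []
    for j in range(data.q):
        labels = data.strata_for(j)
        uniq, inv = np.unique(labels.astype(str), return_inverse=True)
        counts = np.bincount(inv, minlength=len(uniq))
        y_sums = np.bincount(inv, weights=data.phenotypes[:, j], minlength=len(uniq))
        x_sums = np.bincount(inv, weights=x, minlength=len(uniq))
        cells.append(
            {
                str(lab): StratumCell(int(c), float(ys), float(xs))
                for lab, c, ys, xs in zip(uniq, counts, y_sums, x_sums)
            }
        )
    return Stage1Summary(site_id=data.site_id, n=data.n, q=data.q, cells=cells)


def pool_stage1(summaries: Sequence[Stage1Summary]) -> PooledReference:
    """Pool round-1 summaries into reference means for every stratum.

    Pooled means are total-sum over total-count across sites, per phenotype
    and stratum; a stratum present at any site is covered.
    """
    if not summaries:
        raise ValidationError("need at least one stage-1 summary")
    q = summaries[0].q
    for s in summaries:
        if s.q != q:
            raise ValidationError(
                f"site {s.site_id!r} reports q={s.q}, expected {q}"
            )
    n = sum(s.n for s in summaries)
    pooled: list[dict[str, PooledCell]] = []
    for j in range(q):
        acc: dict[str, list[float]] = {}
        for s in summaries:
            for lab, cell in s.cells[j].items():
                tot = acc.setdefault(lab, [0, 0.0, 0.0])
                tot[0] += cell.n
                tot[1] += cell.y_sum
                tot[2] += cell.x_sum
        cells_j: dict[str, PooledCell] = {}
        for lab, (cn, ys, xs) in acc.items():
            if cn == 0:
                raise ValidationError(
                    f"stratum {lab!r} of phenotype {j} has zero pooled count"
                )
            cells_j[lab] = PooledCell(n=cn, y_mean=ys / cn, x_mean=xs / cn)
        pooled.append(cells_j)
    return PooledReference(n=n, q=q, cells=pooled)


# ---------------------------------------------------------------------------
# round 2: per-site score and variance contributions
# ---------------------------------------------------------------------------

def _score_contributions(data: SiteDataset, ref: PooledReference) -> np.ndarray:
    """Per-subject score contributions u (n x q) against pooled reference means."""
    if ref.q != data.q:
        raise ValidationError(
            f"pooled reference has q={ref.q} but site {data.site_id!r} has q={data.q}"
        )
    u = np.empty((data.n, data.q))
    x = data.genotype
    for j in range(data.q):
        labels = data.strata_for(j)
        uniq, inv = np.unique(labels.astype(str), return_inverse=True)
        p = np.empty(len(uniq))
        xbar = np.empty(len(uniq))
        for t, lab in enumerate(uniq):
            cell = ref.cell(j, str(lab))
            p[t] = cell.y_mean
            xbar[t] = cell.x_mean
        u[:, j] = (x - xbar[inv]) * (data.phenotypes[:, j] - p[inv])
    return u


def site_stage2(data: SiteDataset, ref: PooledReference) -> Stage2Summary:
    """Compute one site's score contribution ``S_k`` and variance ``V_k``.

    ``S_k = sum_i u_i`` and ``V_k = sum_i u_i u_i'`` where ``u_i`` centers
    genotype and phenotype at the *pooled* stratum means, so contributions
    add exactly across sites.
    """
    u = _score_contributions(data, ref)
    return Stage2Summary(site_id=data.site_id, S=u.sum(axis=0), V=u.T @ u)


def pool_stage2(
    summaries: Sequence[Stage2Summary],
) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-site contributions into the overall ``S`` and ``V``."""
    if not summaries:
        raise ValidationError("need at least one stage-2 summary")
    q = summaries[0].S.shape[0]
    S = np.zeros(q)
    V = np.zeros((q, q))
    for s in summaries:
        if s.S.shape[0] != q:
            raise ValidationError(
                f"site {s.site_id!r} reports q={s.S.shape[0]}, expected {q}"
            )
        S += s.S
        V += s.V
    return S, V


# ---------------------------------------------------------------------------
# statistic and p-value
# ---------------------------------------------------------------------------

def _diagnose_singular(S: np.ndarray, V: np.ndarray) -> str:
    q = V.shape[0]
    zero_diag = [j for j in range(q) if V[j, j] <= 1e-300]
    if len(zero_diag) == q:
        return (
            "V is identically zero: the SNP is monomorphic or every "
            "phenotype is constant within its strata"
        )
    if zero_diag:
        return (
            f"phenotype component(s) {zero_diag} have zero score variance "
            "(constant phenotype or no genotype variation in their strata)"
        )
    return "V is singular (perfectly collinear phenotype score components)"


def score_statistic(
    S: np.ndarray, V: np.ndarray, *, pseudo_inverse: bool = False
) -> TestResult:
    """Quadratic-form statistic ``T = S V^{-1} S'``.

    By default a singular ``V`` raises :class:`SingularVarianceError` with a
    diagnosis of the degeneracy.  With ``pseudo_inverse=True`` the
    Moore-Penrose inverse is used instead and the degrees of freedom drop to
    ``rank(V)``; the result is flagged ``rank_deficient`` when rank < q.
    """
    S = np.asarray(S, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    q = S.shape[0]
    if V.shape != (q, q):
        raise ValidationError(f"V must be {q}x{q}; got {V.shape}")
    if not np.allclose(V, V.T, atol=1e-10, rtol=0):
        raise ValidationError("V must be symmetric")
    if pseudo_inverse:
        rank = int(np.linalg.matrix_rank(V, hermitian=True))
        if rank == 0:
            raise SingularVarianceError(_diagnose_singular(S, V))
        T = float(S @ scipy.linalg.pinvh(V) @ S)
        return TestResult(
            statistic=max(T, 0.0), df=rank, rank_deficient=rank < q
        )
    # V = sum_i u_i u_i' is Gram, hence PSD; an LU solve keeps exact scalar
    # divisions exact and raises on an exactly singular V.
    if not np.any(np.diag(V)):
        raise SingularVarianceError(_diagnose_singular(S, V))
    try:
        T = float(S @ np.linalg.solve(V, S))
    except np.linalg.LinAlgError:
        raise SingularVarianceError(_diagnose_singular(S, V)) from None
    if not np.isfinite(T):
        raise SingularVarianceError(_diagnose_singular(S, V))
    return TestResult(statistic=max(T, 0.0), df=q)


def pvalue_from_statistic(
    T: float, df: int, *, rank_deficient: bool = False
) -> TestResult:
    """P-value from the chi-square reference with ``df`` degrees of freedom.

    ``p = 1 - Psi_df(T)``; values below 2.22e-16 are reported at that floor
    with ``p_floored`` set, while ``p_raw`` keeps the unfloored value.
    """
    if T < 0:
        raise ValidationError(f"statistic must be nonnegative; got {T}")
    if df < 1:
        raise ValidationError(f"degrees of freedom must be >= 1; got {df}")
    p_raw = float(chi2.sf(T, df))
    floored = p_raw < P_FLOOR
    return TestResult(
        statistic=float(T),
        df=int(df),
        p_value=P_FLOOR if floored else p_raw,
        p_raw=p_raw,
        p_floored=floored,
        rank_deficient=rank_deficient,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def distributed_test(
    sites: Sequence[SiteDataset], *, pseudo_inverse: bool = False
) -> TestResult:
    """Run the full two-round distributed protocol.

    Stage 1 at every site, pool means centrally, stage 2 at every site, pool
    ``S_k``/``V_k``, form the statistic and its p-value.  The result is
    identical (to floating-point summation order) to :func:`pooled_test` on
    the concatenated rows.
    """
    if not sites:
        raise ValidationError("need at least one site")
    ref = pool_stage1([site_stage1(d) for d in sites])
    S, V = pool_stage2([site_stage2(d, ref) for d in sites])
    r = score_statistic(S, V, pseudo_inverse=pseudo_inverse)
    return pvalue_from_statistic(
        r.statistic, r.df, rank_deficient=r.rank_deficient
    )


def pooled_test(
    combined: SiteDataset, *, pseudo_inverse: bool = False
) -> TestResult:
    """Gold-standard mega-analysis path on pooled individual-level rows."""
    return distributed_test([combined], pseudo_inverse=pseudo_inverse)


def concatenate_sites(sites: Sequence[SiteDataset]) -> SiteDataset:
    """Stack the rows of several sites into one pooled dataset."""
    if not sites:
        raise ValidationError("need at least one site")
    q = sites[0].q
    for d in sites:
        if d.q != q:
            raise ValidationError("all sites must share the same phenotypes")
    any_strata = any(d.strata is not None for d in sites)
    strata = None
    if any_strata:
        strata = np.concatenate(
            [
                d.strata
                if d.strata is not None
                else np.full((d.n, q), UNSTRATIFIED, dtype=object)
                for d in sites
            ],
            axis=0,
        )
    return SiteDataset(
        site_id="+".join(d.site_id for d in sites),
        genotype=np.concatenate([d.genotype for d in sites]),
        phenotypes=np.concatenate([d.phenotypes for d in sites], axis=0),
        strata=strata,
        allow_fractional_phenotypes=any(
            d.allow_fractional_phenotypes for d in sites
        ),
    )
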