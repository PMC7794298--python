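"""Domain containers exchanged between sites and the central analyst.

The distributed protocol moves only aggregate quantities between parties:

* :class:`Stage1Summary` — per-stratum counts and sums from one site
  (round 1; in the unadjusted case these reduce to ``n_k``, ``n_k * ybar_k``
  and ``n_k * xbar_k``).
* :class:`PooledReference` — pooled phenotype and genotype means returned by
  the analyst to every site.
* :class:`Stage2Summary` — one site's score contribution ``S_k`` (length q)
  and variance contribution ``V_k`` (q x q).
* :class:`TestResult` — the chi-square statistic, degrees of freedom and
  p-value of the joint pleiotropy test.

No container ever holds patient-level rows except :class:`SiteDataset`,
which never leaves its site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Stratum label used when no covariate adjustment is requested.
UNSTRATIFIED = "__all__"


def _as_2d_labels(strata, n: int, q: int) -> np.ndarray:
    arr = np.asarray(strata, dtype=object)
    if arr.ndim == 1:
        # one shared stratum vector for all phenotypes
        arr = np.repeat(arr[:, None], q, axis=1)
    if arr.shape != (n, q):
        raise ValidationError(
            f"strata must have shape ({n},) or ({n}, {q}); got {arr.shape}"
        )
    return arr.astype(str)


@dataclass
class SiteDataset:
    """Patient-level data held at a single site.

    Parameters
    ----------
    site_id:
        Opaque site label.
    genotype:
        Length-``n`` vector of additive SNP codes in ``{0, 1, 2}``.
    phenotypes:
        ``n x q`` matrix of binary disease indicators.
    strata:
        Optional categorical stratum labels used for covariate adjustment:
        either a length-``n`` vector shared by all phenotypes or an
        ``n x q`` array giving each phenotype its own stratification
        (e.g. a different age-at-onset bin per disease).  ``None`` means
        no adjustment (a single implicit stratum).
    allow_fractional_phenotypes:
        Accept phenotype values anywhere in ``[0, 1]`` instead of strictly
        binary.  Used for prevalence-imputed outcomes; the score-test
        algebra does not require integrality.
    """

    site_id: str
    genotype: np.ndarray
    phenotypes: np.ndarray
    strata: np.ndarray | None = None
    allow_fractional_phenotypes: bool = False

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=float)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.phenotypes.ndim == 1:
            self.phenotypes = self.phenotypes[:, None]
        if self.genotype.ndim != 1 or self.phenotypes.ndim != 2:
            raise ValidationError("genotype must be 1-D and phenotypes 2-D")
        n = self.genotype.shape[0]
        if n == 0:
            raise ValidationError(f"empty site {self.site_id!r}")
        if self.phenotypes.shape[0] != n:
            raise ValidationError(
                f"site {self.site_id!r}: genotype has {n} rows but phenotypes "
                f"has {self.phenotypes.shape[0]}"
            )
        if not np.isin(self.genotype, (0.0, 1.0, 2.0)).all():
            bad = self.genotype[~np.isin(self.genotype, (0.0, 1.0, 2.0))]
            raise ValidationError(
                f"site {self.site_id!r}: genotype must be coded 0/1/2; "
                f"found {bad[:5]!r}"
            )
        y = self.phenotypes
        if self.allow_fractional_phenotypes:
            ok = np.isfinite(y).all() and (y >= 0).all() and (y <= 1).all()
        else:
            ok = bool(np.isin(y, (0.0, 1.0)).all())
        if not ok:
            raise ValidationError(
                f"site {self.site_id!r}: phenotype values must be binary 0/1"
                + (" (or in [0,1] when imputed)" if self.allow_fractional_phenotypes else "")
            )
        if self.strata is not None:
            self.strata = _as_2d_labels(self.strata, n, self.q)

    @property
    def n(self) -> int:
        return self.genotype.shape[0]

    @property
    def q(self) -> int:
        return self.phenotypes.shape[1]

    def strata_for(self, j: int) -> np.ndarray:
        """Stratum labels for phenotype ``j`` (a constant vector if unadjusted)."""
        if self.strata is None:
            return np.full(self.n, UNSTRATIFIED, dtype=object)
        return self.strata[:, j]


@dataclass(frozen=True)
class StratumCell:
    """Counts and sums for one (phenotype, stratum) cell at one site."""

    n: int
    y_sum: float
    x_sum: float

    def __post_init__(self) -> None:
        if self.n < 0 or self.y_sum < -1e-12 or self.y_sum > self.n + 1e-9:
            raise ValidationError(
                f"inconsistent stratum cell: n={self.n}, y_sum={self.y_sum}"
            )


@dataclass
class Stage1Summary:
    """Round-1 message: per-stratum counts and sums from one site.

    ``cells[j]`` maps stratum label -> :class:`StratumCell` for phenotype j.
    """

    site_id: str
    n: int
    q: int
    cells: list[dict[str, StratumCell]]

    def __post_init__(self) -> None:
        if len(self.cells) != self.q:
            raise ValidationError("cells must have one dict per phenotype")
        for j, cj in enumerate(self.cells):
            total = sum(c.n for c in cj.values())
            if total != self.n:
                raise ValidationError(
                    f"site {self.site_id!r}: stratum counts for phenotype {j} "
                    f"sum to {total}, expected n={self.n}"
                )


@dataclass(frozen=True)
class PooledCell:
    """Pooled count and means for one (phenotype, stratum) cell."""

    n: int
    y_mean: float  # pooled phenotype prevalence p_{j,s}, the profiled-out null intercept
    x_mean: float  # pooled genotype mean within the cell


@dataclass
class PooledReference:
    """Pooled means returned to every site after round 1.

    Under the null the fitted intercept of each marginal logistic model is
    profiled out analytically: ``expit(alpha_j)`` equals the pooled phenotype
    prevalence within the relevant stratum, which is exactly ``y_mean`` here.
    """

    n: int
    q: int
    cells: list[dict[str, PooledCell]]

    def cell(self, j: int, label: str) -> PooledCell:
        try:
            return self.cells[j][label]
        except KeyError:
            raise ValidationError(
                f"stratum {label!r} of phenotype {j} is missing from the "
                "pooled reference"
            ) from None


@dataclass
class Stage2Summary:
    """Round-2 message: one site's score and variance contributions."""

    site_id: str
    S: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float).ravel()
        self.V = np.asarray(self.V, dtype=float)
        q = self.S.shape[0]
        if self.V.shape != (q, q):
            raise ValidationError(
                f"V must be {q}x{q} to match S; got {self.V.shape}"
            )
        if not np.allclose(self.V, self.V.T, atol=1e-10, rtol=0):
            raise ValidationError("V must be symmetric")


@dataclass
class TestResult:
    """Outcome of the joint pleiotropy score test.

    ``p_value`` is the reported p-value, floored at 2.22e-16;
    ``p_raw`` retains the unfloored value.
    """

    statistic: float
    df: int
    p_value: float = float("nan")
    p_raw: float = float("nan")
    p_floored: bool = False
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValidationError(f"test statistic must be >= 0; got {self.statistic}")


@dataclass
class SimulationScenario:
    """One multi-site simulation design.

    Defaults reproduce the main power-study conditions: ten sites of 100
    patients each, ten phenotypes with ~40% baseline prevalence
    (``expit(-0.5)``), a low-frequency SNP (MAF 0.05) in Hardy-Weinberg
    equilibrium, and a homogeneous effect vector across sites.
    """

    K: int = 10
    n_per_site: int | Sequence[int] = 100
    q: int = 10
    maf: float | Sequence[float] = 0.05
    pattern: str = "same"
    beta_ref: float = 0.0
    beta0: float = -0.5
    correlation: np.ndarray | None = None
    with_covariates: bool = False
    gamma: float = 0.1
    delta: float = 0.05
    sparse_from_one: bool = False
    seed: int | np.random.SeedSequence | None = None

    def site_sizes(self) -> list[int]:
        if np.isscalar(self.n_per_site):
            return [int(self.n_per_site)] * self.K
        sizes = [int(v) for v in self.n_per_site]
        if len(sizes) != self.K:
            raise ValidationError(
                f"n_per_site has {len(sizes)} entries for K={self.K} sites"
            )
        return sizes

    def site_mafs(self) -> list[float]:
        if np.isscalar(self.maf):
            mafs = [float(self.maf)] * self.K
        else:
            mafs = [float(v) for v in self.maf]
            if len(mafs) != self.K:
                raise ValidationError(
                    f"maf has {len(mafs)} entries for K={self.K} sites"
                )
        for m in mafs:
            if not 0.0 <= m <= 0.5:
                raise ValidationError(f"maf must lie in [0, 0.5]; got {m}")
        return mafs
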