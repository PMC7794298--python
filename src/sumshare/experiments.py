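"""Monte-Carlo evaluation harness: power, type-I error, losslessness.

All experiments share a paired-seed design: a master seed spawns one
substream per repetition, every method in a comparison sees the identical
simulated dataset within a repetition, and the distributed and pooled
arms of the score test consume the same rows by construction.  Rejection
rates therefore differ between methods only through the methods themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import concatenate_sites, distributed_test, pooled_test
from .errors import ValidationError
from .phewas import phewas_mega, phewas_meta
from .simulate import scenario_with_seed, simulate_multisite
from .types import SimulationScenario, SiteDataset

__all__ = [
    "METHODS",
    "PowerResult",
    "estimate_power",
    "compare_methods",
    "lossless_check",
    "sample_size_study",
]


@dataclass
class PowerResult:
    """Empirical rejection rate of one method in one scenario."""

    method: str
    scenario: str
    reps: int
    alpha: float
    rejections: int
    rejection_rate: float
    monte_carlo_se: float

    @classmethod
    def from_counts(
        cls, method: str, scenario: str, reps: int, alpha: float, rejections: int
    ) -> "PowerResult":
        r = rejections / reps
        return cls(
            method=method,
            scenario=scenario,
            reps=reps,
            alpha=alpha,
            rejections=rejections,
            rejection_rate=r,
            monte_carlo_se=float(np.sqrt(r * (1 - r) / reps)),
        )


def _reject_sumshare_distributed(sites: Sequence[SiteDataset], alpha: float) -> bool:
    return distributed_test(sites).p_raw < alpha


def _reject_sumshare_pooled(sites: Sequence[SiteDataset], alpha: float) -> bool:
    return pooled_test(concatenate_sites(sites)).p_raw < alpha


def _reject_phewas_meta(sites: Sequence[SiteDataset], alpha: float) -> bool:
    return phewas_meta(sites, alpha).significant


def _reject_phewas_mega(sites: Sequence[SiteDataset], alpha: float) -> bool:
    return phewas_mega(sites, alpha).significant


METHODS: dict[str, Callable[[Sequence[SiteDataset], float], bool]] = {
    "sumshare-distributed": _reject_sumshare_distributed,
    "sumshare-pooled": _reject_sumshare_pooled,
    "phewas-meta": _reject_phewas_meta,
    "phewas-mega": _reject_phewas_mega,
}


def _rep_seeds(seed, reps: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(reps)


def _scenario_label(s: SimulationScenario) -> str:
    corr = "corr" if s.correlation is not None else "indep"
    return f"{s.pattern}/beta={s.beta_ref}/{corr}/K={s.K}"


def estimate_power(
    method: str,
    scenario: SimulationScenario,
    reps: int = 200,
    alpha: float = 0.05,
    seed=None,
) -> PowerResult:
    """Rejection rate of one method over repeated simulated datasets.

    Per-repetition sub-seeds are spawned deterministically from ``seed``
    (falling back to the scenario's own seed), so two calls with the same
    seed — or with two methods — see identical data.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    decide = METHODS[method]
    if seed is None:
        seed = scenario.seed
    rejections = 0
    for child in _rep_seeds(seed, reps):
        sites = simulate_multisite(scenario_with_seed(scenario, child))
        rejections += bool(decide(sites, alpha))
    return PowerResult.from_counts(method, _scenario_label(scenario), reps, alpha, rejections)


def compare_methods(
    scenarios: Sequence[SimulationScenario],
    methods: Sequence[str] = ("sumshare-distributed", "sumshare-pooled", "phewas-mega"),
    reps: int = 200,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Paired power comparison over a scenario grid.

    Every method is applied to the *same* simulated dataset within each
    repetition, so differences in power are not inflated by simulation
    noise.  Returns a long-format table with one row per (scenario, method).
    """
    for m in methods:
        if m not in METHODS:
            raise ValidationError(f"unknown method {m!r}")
    rows = []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for scen, scen_ss in zip(scenarios, ss.spawn(len(scenarios))):
        counts = {m: 0 for m in methods}
        for child in _rep_seeds(scen_ss, reps):
            sites = simulate_multisite(scenario_with_seed(scen, child))
            for m in methods:
                counts[m] += bool(METHODS[m](sites, alpha))
        for m in methods:
            res = PowerResult.from_counts(m, _scenario_label(scen), reps, alpha, counts[m])
            rows.append(
                {
                    "scenario": res.scenario,
                    "pattern": scen.pattern,
                    "beta": scen.beta_ref,
                    "correlated": scen.correlation is not None,
                    "method": m,
                    "reps": reps,
                    "alpha": alpha,
                    "rejections": res.rejections,
                    "power": res.rejection_rate,
                    "mc_se": res.monte_carlo_se,
                }
            )
    return pd.DataFrame(rows)


def lossless_check(
    n_datasets: int,
    scenario: SimulationScenario | Sequence[SimulationScenario],
    seed=None,
) -> float:
    """Maximum |p_distributed - p_pooled| over freshly simulated datasets.

    The distributed two-round protocol and the pooled single-pass oracle are
    run on the same rows; any discrepancy beyond floating-point summation
    order would break the lossless guarantee.
    """
    scenarios = [scenario] if isinstance(scenario, SimulationScenario) else list(scenario)
    worst = 0.0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for scen, scen_ss in zip(scenarios, ss.spawn(len(scenarios))):
        for child in _rep_seeds(scen_ss, n_datasets):
            sites = simulate_multisite(scenario_with_seed(scen, child))
            p_dist = distributed_test(sites).p_raw
            p_pool = pooled_test(concatenate_sites(sites)).p_raw
            worst = max(worst, abs(p_dist - p_pool))
    return worst


def sample_size_study(
    sizes: Sequence[int],
    scenario: SimulationScenario,
    reps: int = 200,
    alpha: float = 0.05,
    seed=None,
    method: str = "sumshare-distributed",
) -> pd.DataFrame:
    """Power of each dataset analyzed alone versus all datasets integrated.

    Each size becomes a single standalone site; the integrated arm analyzes
    all sites jointly (total n = sum of sizes) with the distributed test.
    Data are shared between arms within a repetition.
    """
    sizes = [int(s) for s in sizes]
    scen_all = SimulationScenario(
        K=len(sizes),
        n_per_site=sizes,
        q=scenario.q,
        maf=scenario.maf,
        pattern=scenario.pattern,
        beta_ref=scenario.beta_ref,
        beta0=scenario.beta0,
        correlation=scenario.correlation,
        with_covariates=scenario.with_covariates,
        gamma=scenario.gamma,
        delta=scenario.delta,
    )
    decide = METHODS[method]
    arms = [(f"site{k + 1} (n={s})", s) for k, s in enumerate(sizes)]
    arms.append(("integrated", sum(sizes)))
    counts = {label: 0 for label, _ in arms}
    for child in _rep_seeds(seed, reps):
        sites = simulate_multisite(scenario_with_seed(scen_all, child))
        for (label, _), site in zip(arms, sites):
            counts[label] += bool(decide([site], alpha))
        counts["integrated"] += bool(decide(sites, alpha))
    rows = []
    for label, n_used in arms:
        res = PowerResult.from_counts(method, label, reps, alpha, counts[label])
        rows.append(
            {
                "arm": label,
                "n": n_used,
                "method": method,
                "reps": reps,
                "alpha": alpha,
                "power": res.rejection_rate,
                "mc_se": res.monte_carlo_se,
            }
        )
    return pd.DataFrame(rows)


def plot_power(table: pd.DataFrame, ax=None):
    """Plot power curves from a :func:`compare_methods` table (one line per method)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, grp in table.groupby("method"):
        grp = grp.sort_values("beta")
        ax.errorbar(grp["beta"], grp["power"], yerr=2 * grp["mc_se"], label=method, marker="o")
    ax.set_xlabel("effect size beta")
    ax.set_ylabel("power")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
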