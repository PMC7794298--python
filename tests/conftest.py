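import numpy as np
import pytest

from sumshare import SimulationScenario, SiteDataset


@pytest.fixture
def worked_dataset() -> SiteDataset:
    """Four-subject dataset whose score test is fully hand-evaluable.

    x = (0,1,2,1), y = (0,1,1,0): xbar = 1, ybar = 0.5, so
    S = sum x*(y - ybar) = 1, V = sum (x-xbar)^2 (y-ybar)^2 = 0.5,
    T = S^2/V = 2.0 and p = P(chi2_1 > 2) = 0.15729920705028105.
    """
    return SiteDataset(
        site_id="worked",
        genotype=np.array([0, 1, 2, 1]),
        phenotypes=np.array([[0.0], [1.0], [1.0], [0.0]]),
    )


@pytest.fixture
def null_scenario() -> SimulationScenario:
    """The calibration design: 10 sites x 100 subjects, 10 null phenotypes."""
    return SimulationScenario(K=10, n_per_site=100, q=10, maf=0.05, pattern="null")


def random_sites(rng: np.random.Generator, k: int = 3, n_min: int = 8, q: int = 3):
    """Small multi-site datasets with guaranteed genotype/phenotype variation."""
    sites = []
    for s in range(k):
        n = int(rng.integers(n_min, n_min + 20))
        x = rng.integers(0, 3, size=n).astype(float)
        x[0], x[1] = 0.0, 1.0  # ensure genotype variation overall
        y = (rng.random((n, q)) < 0.4).astype(float)
        y[0] = 0.0
        y[1] = 1.0
        sites.append(SiteDataset(site_id=f"s{s}", genotype=x, phenotypes=y))
    return sites
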