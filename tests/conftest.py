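import numpy as np
import pandas as pd
import pytest

import embermap as em


@pytest.fixture(scope="session")
def grid10():
    return em.generate_lattice(10, 10, seed=1)


@pytest.fixture(scope="session")
def small_scenario(grid10):
    """A modest synthetic registry: 100 areas, 1991-2007."""
    cfg = em.ScenarioConfig(n_areas=100, seed=5)
    counts, truth = em.simulate_epidemic(cfg, grid10)
    return cfg, counts, truth


@pytest.fixture()
def toy_counts():
    """Two areas, one year, one band, both methods, both sexes."""
    rows = []
    for area, n in (("a", 50_000.0), ("b", 25_000.0)):
        for sex in ("male", "female"):
            for method, d in (("charcoal", 2), ("non_charcoal", 5)):
                rows.append((area, 2000, sex, "40-44", method, d, n))
    return pd.DataFrame(
        rows,
        columns=["area_id", "year", "sex", "age_band", "method", "deaths", "person_years"],
    )


@pytest.fixture()
def pair_graph():
    return em.AreaGraph(["a", "b"], {"a": ["b"], "b": ["a"]},
                        urban_level={"a": 1, "b": 7})


def brute_force_moran(x, W):
    """Double-loop Moran's I oracle (dense weights)."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    S0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            S0 += W[i, j]
    den = ((x - xbar) ** 2).sum()
    return (n / S0) * num / den
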