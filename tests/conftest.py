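import numpy as np
import pytest

import recsim as rs


@pytest.fixture(scope="session")
def maize_params() -> rs.MeiosisParams:
    """Bundled study conditions: maize genome, 125 kb synthetic map."""
    return rs.default_params(map_seed=0)


@pytest.fixture(scope="session")
def toy_genome() -> rs.Genome:
    return rs.build_genome([("1", 100_000_000), ("2", 60_000_000)])


@pytest.fixture(scope="session")
def toy_params(toy_genome) -> rs.MeiosisParams:
    """Toy genome with a uniform placement map and default counts."""
    grid = rs.make_window_grid(toy_genome, 1_000_000)
    rates = {c: np.ones(grid.n_windows(c)) for c in toy_genome.ids}
    return rs.MeiosisParams(
        count_dist=rs.CrossoverCountDistribution.from_raw(),
        rec_map=rs.RecombinationMap(grid, rates),
    )


def degenerate_count_dist(k: int, kmax: int = 3) -> rs.CrossoverCountDistribution:
    p = np.zeros(kmax + 1)
    p[k] = 1.0
    return rs.CrossoverCountDistribution(np.arange(kmax + 1), p)
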