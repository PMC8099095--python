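import numpy as np
import pytest

from isoprov.compilation import site_average
from isoprov.grids import GridSpec, extract_at_points
from isoprov.model import build_regression_dataset
from isoprov.synthetic import WorldSpec, make_covariates, sample_sites


def small_worldspec(seed: int = 7, n: int = 40, n_decoys: int = 3) -> WorldSpec:
    grid = GridSpec(crs="local", cell_size=10_000.0, xmin=0.0,
                    ymax=n * 10_000.0, nrows=n, ncols=n)
    return WorldSpec(grid=grid, seed=seed, n_decoys=n_decoys)


@pytest.fixture(scope="session")
def world_small():
    """A 40x40 synthetic world shared by the model-level tests."""
    return make_covariates(small_worldspec())


@pytest.fixture(scope="session")
def dataset_small(world_small):
    """Regression dataset from 80 sites x 4 records on the small world."""
    ws = world_small.ws
    records = sample_sites(world_small, n_sites=80, per_site_n=4,
                           rng=ws.streams()["sites"])
    sites = site_average(records)
    cov = extract_at_points(
        world_small.stack,
        [(s.site_id, s.latitude * 1e5, s.longitude * 1e5) for s in sites])
    candidates = [n for n in world_small.stack.names if n != "r.distance"]
    return build_regression_dataset(sites, cov, candidates)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
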