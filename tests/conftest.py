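import numpy as np
import pytest

from hippodiff import geometry as geo
from hippodiff import synthetic_cohort as sc
from hippodiff.signal_models import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def rect_domain():
    dom = sc.generate_domain((16, 12, 10), seed=0, curved=False)
    for axis in ("AP", "PD", "IO"):
        geo.solve_laplace(dom, axis)
    return dom


@pytest.fixture(scope="session")
def curved_domain():
    dom = sc.generate_domain((18, 12, 9), seed=5, curved=True)
    for axis in ("AP", "PD", "IO"):
        geo.solve_laplace(dom, axis)
    return dom


@pytest.fixture(scope="session")
def surface(curved_domain):
    return geo.build_midthickness_surface(curved_domain, n_ap=15, n_pd=10)


@pytest.fixture(scope="session")
def full_surface(curved_domain):
    """Default-resolution unfolded grid (121 x 60 = 7260 vertices)."""
    return geo.build_midthickness_surface(curved_domain)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
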