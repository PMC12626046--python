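import numpy as np
import pytest

from nirsdcs import ForwardModelSpec, ProbeGeometry
from nirsdcs.synthetic import gaussian_irf
from nirsdcs.tdnirs import compute_irf_metrics


@pytest.fixture(scope="session")
def spec():
    return ForwardModelSpec()


@pytest.fixture(scope="session")
def geom():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def irf_shape(spec):
    """Unit-area Gaussian IRF on the default grid (FWHM 200 ps at 3.9 ns)."""
    return gaussian_irf(spec.time_edges_ns)


@pytest.fixture(scope="session")
def irf_record(spec, irf_shape):
    return compute_irf_metrics(spec.time_edges_ns, irf_shape * 1e6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
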