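import numpy as np
import pytest

from csinet.forward import AcquisitionGeometry
from csinet.phantoms import PriorBackground, TissueLabelMap, make_phantom
from csinet.pipeline import fixture_suite


@pytest.fixture(scope="session")
def fixtures_dir(tmp_path_factory):
    """Tiny deterministic assets shared across the suite."""
    return fixture_suite(tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def small_geometry():
    """Compact acquisition for fast solver tests (D = 6.4 x 6.4 cm)."""
    return AcquisitionGeometry.circular(domain_half_width=3.2, n_tx=8, n_rx=8)


@pytest.fixture(scope="session")
def desk_geometry():
    """Desk-scale acquisition matching a 64 x 64 grid at 0.2 cm."""
    return AcquisitionGeometry.circular(domain_half_width=6.4)


def homogeneous_prior(grid_shape, pixel_size, eps, model_id="I"):
    bg = np.full(grid_shape, complex(eps))
    return PriorBackground(
        eps_n_real=bg.real.copy(),
        eps_n_imag=(-bg.imag).copy(),
        region_labels=TissueLabelMap(
            np.zeros(grid_shape, dtype=np.int8), pixel_size, model_id
        ),
        boundary_jitter=0.0,
    )


@pytest.fixture(scope="session")
def small_phantom():
    """Deterministic 64 x 64 single-tumor phantom (model I)."""
    rng = np.random.default_rng(42)
    return make_phantom("I", (64, 64), 0.2, rng, n_tumors=1)
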