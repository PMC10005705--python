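import numpy as np
import pytest

from osteomech.bending import TubeGeometry
from osteomech.synthetic import BendingGroundTruth, DMAProtocol, SLSParams


@pytest.fixture
def ovx_geometry() -> TubeGeometry:
    """OVX-group mean midshaft: outer diameter 1.37 mm, inner 0.90 mm."""
    return TubeGeometry(outer_radius=0.685, inner_radius=0.45, span=6.0)


@pytest.fixture
def control_geometry() -> TubeGeometry:
    """Control-group mean midshaft: outer diameter 1.46 mm, inner 0.86 mm."""
    return TubeGeometry(outer_radius=0.73, inner_radius=0.43, span=6.0)


@pytest.fixture
def sls_params() -> SLSParams:
    """Noise-free three-parameter solid used across the DMA tests."""
    return SLSParams(E_inst=3.0, E_eq=1.0, tau=1.0)


@pytest.fixture
def protocol() -> DMAProtocol:
    return DMAProtocol()


def make_truth(
    geometry: TubeGeometry,
    e_true: float = 4.63,
    yield_load: float = 12.0,
    hardening: float = 10.0,
    pyd: float = 0.47,
    popins: tuple[tuple[float, float], ...] = (),
) -> BendingGroundTruth:
    """Bending ground truth with fracture placed ``pyd`` beyond the kink."""
    e_mpa = e_true * 1000.0
    import osteomech.bending as bd

    s = 48.0 * e_mpa * bd.moment_of_inertia(geometry) / geometry.span**3
    d_y = yield_load / s
    return BendingGroundTruth(
        E_true=e_true,
        geometry=geometry,
        yield_load=yield_load,
        hardening_slope=hardening,
        fracture_displacement=d_y + pyd,
        popin_events=popins,
    )
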