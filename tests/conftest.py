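import numpy as np
import pytest

from cuppingct import (
    CylinderPhantom,
    EnergySpectrum,
    ScannerGeometry,
    default_grid,
    iodinated_water_lac,
    normalize_source,
    tube_source_100kv,
)


@pytest.fixture(scope="session")
def tube_source():
    """100 kV filtered tube spectrum with two characteristic lines."""
    return tube_source_100kv()


@pytest.fixture(scope="session")
def ki_lac():
    """KI-solution-like LAC: iodine K-edge at 33.2 keV, mu_1(0) ~ 0.96 1/cm."""
    return iodinated_water_lac()


@pytest.fixture(scope="session")
def two_line_pair():
    """Exactly solvable pair: equal-weight lines at 40 and 70 keV seeing
    mu = 0.2 and mu = 0.8 1/cm respectively.

    The LAC is piecewise constant with its step recorded as an edge, so the
    quadrature reproduces I(s) = (exp(-0.2 s) + exp(-0.8 s))/2 exactly.
    """
    grid = default_grid(10.0, 100.0, 0.5)
    vals = np.zeros_like(grid)
    vals[np.argmin(np.abs(grid - 40.0))] = 1.0
    vals[np.argmin(np.abs(grid - 70.0))] = 1.0
    source = normalize_source(EnergySpectrum(grid, vals))
    mu = np.where(grid < 55.0, 0.2, 0.8)
    lac = EnergySpectrum(grid, mu, edge_energies_keV=(55.0,))
    return source, lac


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced scanner for fast reconstruction tests."""
    return ScannerGeometry(delta_cm=0.01, n_detectors=128, n_angles=201, image_size_vox=128)


@pytest.fixture(scope="session")
def full_geometry():
    """The reference configuration: 0.01 cm pitch, 512 detectors, 805 angles."""
    return ScannerGeometry()


@pytest.fixture(scope="session")
def ki_phantom(ki_lac):
    return CylinderPhantom(0.9, ki_lac)
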