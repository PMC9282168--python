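import numpy as np
import pytest

from thetaplace.ec import GridCellParams


def make_single_field_cell(center=(0.5, 0.5), spacing=0.5, orientation=0.0,
                           amplitude=1.0, k_phi=1.0, phi0=320.0,
                           delta_phi=300.0):
    """A grid cell whose lattice vertex (0, 0) sits exactly at ``center``
    (offset = center), convenient for single-field geometry tests."""
    amps = np.full((7, 7), amplitude)
    return GridCellParams(spacing=spacing, orientation=orientation,
                          offset=np.asarray(center, dtype=float),
                          k_phi=k_phi, phi0=phi0, delta_phi=delta_phi,
                          i0=-3, j0=-3, amplitudes=amps)


@pytest.fixture
def illustrative_cell():
    """The illustrative grid cell: k_phi=1, phi0=320 deg, delta_phi=300
    deg, R=0.16 m (spacing 0.5 m), theta at 10 Hz."""
    return make_single_field_cell()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
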