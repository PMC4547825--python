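import numpy as np
import pytest

from cryocdi import (DensityVolume, PhantomSpec, default_phantom_spec,
                     generate_phantom, make_geometry)


@pytest.fixture(scope="session")
def production_geometry():
    """The production experiment: 8 keV, 5.29 m camera, 55 um pixels, 516^2."""
    return make_geometry(8.0, 5.29, 55.0, 516)


@pytest.fixture(scope="session")
def desk_geometry():
    """A 32-pixel detector with the production field of view (desk scale)."""
    return make_geometry(8.0, 5.29, 55.0 * 516 / 32, 32,
                         beamstop_radius_px=0, gap_width_px=0)


@pytest.fixture(scope="session")
def small_phantom():
    """Band-limited banana-cell phantom on 32^3, support inside the central half."""
    spec = default_phantom_spec(scale=0.09)
    spec.texture_amplitude = 0.0
    spec.edge_sigma_um = 0.03
    return generate_phantom(spec, 32, 30.0)


@pytest.fixture(scope="session")
def sphere_volume():
    """A smooth spherical cell (radius 0.15 um) on 48^3 at 30 nm voxels."""
    spec = PhantomSpec(cell_semi_axes_um=(0.15, 0.15, 0.15),
                       centerline_curvature=0.0, edge_sigma_um=0.06)
    return generate_phantom(spec, 48, 30.0)


@pytest.fixture()
def uniform_cube_volume():
    values = np.zeros((32, 32, 32))
    values[10:22, 10:22, 10:22] = 1.0
    return DensityVolume(values, 30.0)
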