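import numpy as np
import pytest

from ldrtplan.core import Grid, ImageVolume, StructureMask
from ldrtplan.dose import DoseGrid


def make_grid(shape=(20, 20, 20), spacing=(2.0, 2.0, 2.0), origin=(0.0, 0.0, 0.0)):
    return Grid(shape, spacing, origin)


def box_mask(grid, lo_mm, hi_mm, name="box", role="PTV"):
    """Voxels whose centers lie inside the closed box [lo_mm, hi_mm] per axis."""
    x, y, z = grid.meshgrid()
    m = (
        (x >= lo_mm[0]) & (x <= hi_mm[0])
        & (y >= lo_mm[1]) & (y <= hi_mm[1])
        & (z >= lo_mm[2]) & (z <= hi_mm[2])
    )
    return StructureMask(name, m, grid, role=role)


def uniform_dose(grid, value, prescription=1.0):
    return DoseGrid(ImageVolume(np.full(grid.shape, float(value)), grid, "Gy"),
                    prescription)


def dose_from_array(grid, arr, prescription=1.0):
    return DoseGrid(ImageVolume(np.asarray(arr, dtype=float), grid, "Gy"), prescription)


@pytest.fixture
def grid20():
    return make_grid()


@pytest.fixture
def noise_free_phantom():
    """Three well-separated lesions, zero PET noise, constant liver uptake."""
    from ldrtplan.phantom import BodySpec, LesionSpec, LiverSpec, PhantomSpec, generate_phantom

    spec = PhantomSpec(
        grid_shape=(48, 48, 72),
        spacing=(4.0, 4.0, 4.0),
        body=BodySpec(center_xy=(94.0, 94.0), radii_xy=(85.0, 70.0), z_range=(0.0, 284.0)),
        liver=LiverSpec(center=(125.0, 94.0, 190.0), radii=(35.0, 28.0, 30.0),
                        suv_mean=1.0, suv_sd=0.0),
        lesions=(
            LesionSpec("a", (70.0, 94.0, 60.0), (10.0, 10.0, 10.0), 5.0),
            LesionSpec("b", (94.0, 70.0, 140.0), (8.0, 12.0, 10.0), 5.0),
            LesionSpec("c", (115.0, 94.0, 240.0), (12.0, 9.0, 8.0), 5.0),
        ),
        background_suv_mean=0.8,
        background_suv_sd=0.0,
        seed=11,
    )
    return generate_phantom(spec)
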