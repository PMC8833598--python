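import numpy as np
import pytest

from mrteud import (
    TissueParams,
    VoxelGrid,
    arrange_beams,
    generate_phantom,
)
from mrteud.gridio import packaged_data_path
from mrteud.phantom import PhantomSpec, SphereSpec
from mrteud.radiobiology import load_tissue_table


@pytest.fixture(scope="session")
def default_params():
    return TissueParams("default", alpha=0.1, beta=0.05)


@pytest.fixture(scope="session")
def registry():
    return load_tissue_table(packaged_data_path("tissue_params.csv"))


@pytest.fixture(scope="session")
def water_grid():
    """Homogeneous 5x5x1 water grid of 2 mm voxels centred on the origin."""
    return VoxelGrid(np.ones((5, 5, 1)), (2.0, 2.0, 2.0), origin=(-4.0, -4.0, 0.0))


@pytest.fixture(scope="session")
def small_phantom():
    """Compact phantom with a PTV-overlapping OAR, for end-to-end tests."""
    spec = PhantomSpec(
        shape=(24, 24, 6),
        spacing_mm=(2.0, 2.0, 2.0),
        body_radius_mm=20.0,
        target=SphereSpec("PTV", (0.0, 4.0, 0.0), 12.0),
        oars=(SphereSpec("brain_stem", (0.0, -4.0, 0.0), 8.0),),
    )
    return generate_phantom(spec, seed=0)


@pytest.fixture(scope="session")
def small_plan(small_phantom, registry):
    """Three cross-firing conformal beams on the small phantom."""
    density, labels = small_phantom
    beams = arrange_beams(
        [0.0, 120.0, 240.0],
        target_mask=labels.structure("PTV"),
        grid=density,
        isocenter=(0.0, 4.0, 0.0),
        entrance_peak_dose=50.0,
        dilation_voxels=1,
    )
    return density, labels, beams
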