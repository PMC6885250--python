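import numpy as np
import pytest

from tmscoilopt import model_io as mio
from tmscoilopt import phantom as ph


def voxel_sphere(radius_mm: float, spacing_mm: float,
                 label: int = 1, name: str = "Skin") -> mio.VoxelModel:
    """Voxelized solid sphere, bottom at z = 0, centered in X/Y."""
    pad = 2
    n = int(np.ceil(2 * radius_mm / spacing_mm)) + 2 * pad
    origin = np.array([-n * spacing_mm / 2, -n * spacing_mm / 2,
                       -pad * spacing_mm])
    c = [origin[a] + (np.arange(n) + 0.5) * spacing_mm for a in range(3)]
    X, Y, Z = np.meshgrid(*c, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + (Z - radius_mm) ** 2)
    labels = (r <= radius_mm).astype(np.uint8) * label
    return mio.VoxelModel(labels=labels, spacing=spacing_mm, origin=origin,
                          label_names={label: name})


@pytest.fixture(scope="session")
def sphere40() -> mio.VoxelModel:
    """Solid 40 mm sphere at 1 mm spacing."""
    return voxel_sphere(40.0, 1.0)


@pytest.fixture(scope="session")
def gyrified_scenario():
    """Default gyrified phantom with its ROI and initial pose (seed 1)."""
    spec = ph.PhantomSpec(seed=1)
    model, roi, ip = ph.make_gyrified_phantom(spec)
    return spec, model, roi, ip
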