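import numpy as np
import pytest

from canopyseg import Affine, CrownSet, HyperCube, RasterGrid, SceneConfig, make_scene


@pytest.fixture(scope="session")
def scene():
    """Default synthetic scene: 25 non-overlapping radial crowns, 4 species."""
    return make_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def species_split(scene):
    """Stratified train/test crown split of the default scene.

    Species are assigned round-robin over crown ids, so alternating blocks
    of one full species cycle keeps every species in both halves.
    """
    crowns = list(scene.crowns)
    k = len(scene.config.species)
    train = CrownSet([c for i, c in enumerate(crowns) if (i // k) % 2 == 0], crs=scene.crowns.crs)
    test = CrownSet([c for i, c in enumerate(crowns) if (i // k) % 2 == 1], crs=scene.crowns.crs)
    return train, test


def toy_cube(values_by_band, wavelengths, pixel_size=1.0, crs="EPSG:32617"):
    """Build a HyperCube from a list of 2-D arrays."""
    arrays = [np.asarray(v, dtype=float) for v in values_by_band]
    transform = Affine.north_up(0.0, arrays[0].shape[0] * pixel_size, pixel_size)
    bands = [RasterGrid(a, transform, crs=crs) for a in arrays]
    return HyperCube(bands, np.asarray(wavelengths, dtype=float))


@pytest.fixture
def make_toy_cube():
    return toy_cube
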