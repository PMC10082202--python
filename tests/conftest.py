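import warnings

import numpy as np
import pytest

import mfscan as mf

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def clean_optics():
    """Noise and vignetting off — deterministic oracle renders."""
    return mf.OpticsModel().clean()


@pytest.fixture(scope="session")
def default_optics():
    return mf.OpticsModel()


@pytest.fixture(scope="session")
def flat_scene():
    """Flat membrane, a few well-separated cells of each class."""
    surf = mf.generate_surface(80.0, amplitude_um=0.0, seed=0)
    return mf.populate_scene(surf, 8, 3, 0, 0, seed=7, min_distance_um=18, margin_um=10)


def make_tile_scene(seed, n_mctc=4, n_caf=2, n_pore=2, n_precip=2, amplitude_um=15.0):
    """One camera-FOV scene: a 300 µm wavy membrane whose cells are confined
    to the central ~46 µm so a 224-px tile at stage (124.2, 124.2) sees them
    all.  The membrane's correlation length (500 µm) exceeds the field, so
    each seed gives a nearly flat surface at a random height offset."""
    surf = mf.generate_surface((300.0, 300.0), amplitude_um=amplitude_um,
                               correlation_length_um=500.0, seed=seed)
    return mf.populate_scene(surf, n_mctc, n_caf, n_pore, n_precip, seed=seed,
                             min_distance_um=11.0, margin_um=127.0)


TILE_STAGE_UM = (124.2, 124.2)
TILE_SHAPE = (224, 224)


@pytest.fixture(scope="session")
def wavy_tile_scene():
    return make_tile_scene(seed=42)


def cells_of(scene):
    return [o for o in scene.objects if o.cls in ("mCTC", "CAF")]
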