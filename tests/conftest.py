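"""Shared fixtures: small synthetic phantoms and transport media.

All fixtures are generated programmatically; nothing is loaded from disk.
Session scope keeps the expensive phantoms and Monte Carlo runs shared
across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirpdt.embedding import embed_tumor
from nirpdt.optics import OpticsTable, assign_optics
from nirpdt.phantom import LabeledVolume, TissueLabel
from nirpdt.synthetic import SyntheticParams, generate_phantom

# geometry that fits a 120^3 grid at 0.33 mm pitch (39.6 mm extent) while
# leaving room for a 7-mm tumor plus 9-mm host block down to 25 mm depth
HOST_SEMI_AXES = (17.0, 17.0, 36.0)
HOST_GRID = (120, 120, 120)
PITCH = 0.33


def make_host_phantom(depth_mm: float, target_density: float = 0.0,
                      seed: int = 3) -> tuple:
    """Pendant breast with a guaranteed duct host block at ``depth_mm``."""
    params = SyntheticParams(semi_axes_mm=HOST_SEMI_AXES,
                             target_density=target_density,
                             host_depth_mm=depth_mm, seed=seed)
    vol, prov = generate_phantom(params, HOST_GRID, PITCH)
    return vol, prov


@pytest.fixture(scope="session")
def host_phantom_20():
    """Homogeneous-fat breast with a duct host block at 20 mm depth."""
    return make_host_phantom(20.0)


@pytest.fixture(scope="session")
def embedded_20(host_phantom_20):
    """Host phantom with the 7-mm tumor embedded."""
    vol, _ = host_phantom_20
    vol_t, spec = embed_tumor(vol)
    assert spec is not None
    return vol_t, spec


@pytest.fixture(scope="session")
def textured_phantom():
    """Breast phantom with random duct texture at density 0.30."""
    params = SyntheticParams(semi_axes_mm=HOST_SEMI_AXES, target_density=0.30,
                             host_depth_mm=20.0, seed=7)
    return generate_phantom(params, HOST_GRID, PITCH)


def fat_block(shape=(20, 20, 60), pitch=PITCH) -> LabeledVolume:
    """Homogeneous fat block (no skin, no air) for transport validation."""
    return LabeledVolume(
        np.full(shape, int(TissueLabel.FAT), dtype=np.uint8), pitch)


@pytest.fixture()
def scatterfree_fat_optvol():
    """All-fat medium with scattering switched off (Beer-Lambert route)."""
    table = OpticsTable().replace(TissueLabel.FAT, mu_s=0.0)
    return assign_optics(fat_block(), table)


@pytest.fixture()
def fat_optvol():
    """All-fat scattering medium at the standard 808-nm properties."""
    return assign_optics(fat_block(shape=(40, 40, 40)))
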