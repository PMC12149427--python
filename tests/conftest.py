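import numpy as np
import pytest

from octhrf.model import LayerSurfaces, ScanGeometry
from octhrf.synth import PhantomSpec


@pytest.fixture
def small_geometry():
    """Compact volume that still contains the full 1-mm and part of the
    3-mm disc (en-face half-extents ~0.9 mm)."""
    return ScanGeometry(
        n_bscans=31,
        n_ascans=160,
        depth_px=200,
        axial_px_um=4.0,
        lateral_px_um=12.0,
        bscan_spacing_um=60.0,
    )


@pytest.fixture
def flat_surfaces(small_geometry):
    g = small_geometry
    shape = (g.n_bscans, g.n_ascans)
    return LayerSurfaces(
        np.full(shape, 100.0), np.full(shape, 400.0), np.full(shape, 600.0)
    )


@pytest.fixture
def small_phantom_spec(small_geometry):
    return PhantomSpec(
        geometry=small_geometry,
        n_hrf=8,
        n_oversized=2,
        n_undersized=2,
        ilm_base_um=150.0,
        oplhfl_base_um=450.0,
        rpe_base_um=600.0,
        pit_depth_um=60.0,
        seed=3,
    )
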