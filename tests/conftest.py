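from __future__ import annotations

import numpy as np
import pytest

from cardiomotion.frames import RFFrame
from cardiomotion.segmentation import PixelGrid, segment_myocardium
from cardiomotion.synthrf import PsfParams, Region, make_lv_phantom, make_scatterer_field, render_rf_frame


@pytest.fixture(scope="session")
def psf() -> PsfParams:
    return PsfParams()


@pytest.fixture(scope="session")
def speckle_frame(psf) -> RFFrame:
    """A rendered speckle frame over a 6 x 6 mm region (session-cached)."""
    region = Region(0.0, 6.0, -3.0, 3.0)
    scene = make_scatterer_field(region, density_per_mm2=350.0, seed=11)
    return render_rf_frame(scene, psf)


def random_frame_pair(seed: int, shape=(64, 32)) -> tuple[RFFrame, RFFrame]:
    """White-noise RF frame pair with metadata giving a 4-sample wavelength."""
    rng = np.random.default_rng(seed)
    meta = dict(center_frequency=21e6, sampling_frequency=84e6, pitch=0.09)
    return (
        RFFrame(samples=rng.normal(size=shape), **meta),
        RFFrame(samples=rng.normal(size=shape), **meta),
    )


@pytest.fixture(scope="session")
def phantom_segmentation():
    """Default half-elliptical annulus phantom plus its full segmentation.

    Grid spacing 0.05 mm; layer masks for both 3 and 10 layers.  Shared
    across segmentation/transmural tests (read-only).
    """
    endo_kp, epi_kp, scene = make_lv_phantom(
        inner_axes=(4.0, 6.0), outer_axes=(6.0, 8.0), center=(1.0, 0.0), seed=5
    )
    grid = PixelGrid.regular((0.0, 10.0), (-7.0, 7.0), (0.05, 0.05))
    seg = segment_myocardium(endo_kp, epi_kp, grid)
    return endo_kp, epi_kp, scene, grid, seg


@pytest.fixture(scope="session")
def circular_annulus():
    """Half-circular annulus r=10, R=16 mm segmented on a 0.1 mm grid."""
    endo_kp, epi_kp, _ = make_lv_phantom(
        (10.0, 10.0), (16.0, 16.0), center=(0.0, 0.0), density_per_mm2=1.0, seed=0
    )
    grid = PixelGrid.regular((-0.5, 17.0), (-17.0, 17.0), (0.1, 0.1))
    seg = segment_myocardium(endo_kp, epi_kp, grid, n_points=800)
    return grid, seg
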