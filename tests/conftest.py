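"""Shared fixtures: small deterministic phantoms and a segmentation helper."""

from __future__ import annotations

import numpy as np
import pytest

from biofilmflow.phantom import ColonySpec, NoiseSpec, add_colony, add_substratum, make_noise_volume
from biofilmflow.preprocess import detect_substratum, flatten
from biofilmflow.segmentation import binarise, compute_histogram, find_threshold, remove_outliers
from biofilmflow.volume import IntensityVolume


@pytest.fixture(scope="session")
def noise_spec() -> NoiseSpec:
    return NoiseSpec(mean_level=30.0, sigma=5.0, seed=1)


@pytest.fixture(scope="session")
def colony_phantom(noise_spec):
    """Flat-substratum phantom with three well-separated colonies.

    The biofilm intensity mean sits 12 sigma above the noise mean
    (i.e. well past 5 sigma separation), with streamers thick enough to
    be physically plausible.  Returns (volume, substratum depth map,
    ground truth).
    """
    vol = make_noise_volume((48, 128, 128), noise_spec)
    vol, depth = add_substratum(vol, 0.0, 200, 2)
    truth = None
    rng = np.random.default_rng(42)
    for cx, cy, r, h, lean, sl in [
        (30, 30, 11, 30, 10, 12),
        (80, 90, 12, 32, 10, 12),
        (95, 35, 10, 28, 10, 12),
    ]:
        spec = ColonySpec(
            footprint_centre=(cx, cy),
            footprint_radius=r,
            height=h,
            lean_angle=lean,
            streamer_length=sl,
            streamer_thickness=3,
            biofilm_intensity_mean=90.0,
            biofilm_intensity_sigma=8.0,
        )
        vol, truth = add_colony(vol, spec, noise_spec, depth, truth, rng=rng)
    return vol, depth, truth


def segment_phantom(vol: IntensityVolume, drop_bottom: int = 1):
    """Standard measurement chain used by several tests.

    Detect the substratum, flatten, drop the substratum layer, threshold
    on the histogram inflexion, binarise, and denoise.  Returns the
    filtered binary volume and the threshold result.
    """
    sub = detect_substratum(vol)
    flat = flatten(vol, sub)
    body = IntensityVolume(
        flat.data[drop_bottom:].copy(), vol.voxel_lateral, vol.voxel_axial
    )
    thr = find_threshold(compute_histogram(body))
    binary = binarise(body, thr)
    return remove_outliers(binary), thr
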