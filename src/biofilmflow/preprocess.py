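"""Volume preparation: rotation, substratum detection, flattening, registration.

The substratum is located per column as the brightest voxel along z and
smoothed with a generous 2D median filter (disk of radius 11 pixels by
default).  Flattening shifts each column down by an integer number of
voxels so the substratum sits at ``z = 0`` — no sub-voxel resampling, so
binarisation-relevant intensities and column heights are preserved
exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volume import BinaryVolume, IntensityVolume, quantise_intensity

DEFAULT_MEDIAN_RADIUS = 11


@dataclass
class SubstratumMap:
    """Detected per-column substratum depth.

    ``low_confidence`` is set when the raw per-column argmax disagrees
    with the median-filtered surface over a large fraction of the field
    (``outlier_fraction``), which happens on scans without a clear
    plane (e.g. pure noise).
    """

    depth: np.ndarray  # int, shape (ny, nx)
    low_confidence: bool = False
    outlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 2:
            raise ValueError("depth map must be 2D")
        if self.depth.min() < 0:
            raise ValueError("depths must be non-negative")


def rotate_volume(
    vol: IntensityVolume,
    angle_a: float,
    angle_b: float,
    *,
    convert_anisotropy: bool = True,
) -> IntensityVolume:
    """Rotate by two preset angles (degrees) about the y and x axes.

    ``angle_a`` rotates in the (z, x) plane, ``angle_b`` in the (z, y)
    plane; a substratum plane whose depth rises downstream at +5 degrees
    is levelled by ``angle_a = -5``.  Angles are physical; because the
    axial voxel pitch differs from the lateral pitch, they are converted
    to index-space angles before rotation unless
    ``convert_anisotropy=False``.  Trilinear interpolation; out-of-range
    samples take the background mode.
    """
    for angle in (angle_a, angle_b):
        if not -45.0 < angle < 45.0:
            raise ValueError("rotation angles must lie in (-45, 45) degrees")
    if angle_a == 0.0 and angle_b == 0.0:
        return vol.copy()
    aspect = vol.voxel_lateral / vol.voxel_axial

    def to_index_angle(angle: float) -> float:
        if not convert_anisotropy:
            return angle
        return math.degrees(math.atan(math.tan(math.radians(angle)) * aspect))

    fill = float(vol.background_mode())
    data = vol.data.astype(np.float32)
    if angle_a != 0.0:
        data = ndimage.rotate(
            data,
            -to_index_angle(angle_a),
            axes=(0, 2),
            reshape=False,
            order=1,
            mode="constant",
            cval=fill,
        )
    if angle_b != 0.0:
        data = ndimage.rotate(
            data,
            -to_index_angle(angle_b),
            axes=(0, 1),
            reshape=False,
            order=1,
            mode="constant",
            cval=fill,
        )
    return IntensityVolume(quantise_intensity(data), vol.voxel_lateral, vol.voxel_axial)


def detect_substratum(
    vol: IntensityVolume,
    median_radius: int = DEFAULT_MEDIAN_RADIUS,
    *,
    outlier_tolerance: int = 2,
    low_confidence_fraction: float = 0.25,
) -> SubstratumMap:
    """Per-column argmax of intensity along z, median-filtered over (x, y).

    The median filter uses a disk footprint of the given radius with
    nearest-edge padding.  Ties in the argmax resolve to the lowest z.
    """
    raw = np.argmax(vol.data, axis=0).astype(np.int64)
    if median_radius > 0:
        filtered = ndimage.median_filter(
            raw, footprint=disk(median_radius), mode="nearest"
        )
    else:
        filtered = raw
    frac = float(np.mean(np.abs(raw - filtered) > outlier_tolerance))
    return SubstratumMap(
        depth=filtered,
        low_confidence=frac > low_confidence_fraction,
        outlier_fraction=frac,
    )


def flatten(vol: IntensityVolume, sub: SubstratumMap) -> IntensityVolume:
    """Shift each column down so its substratum voxel sits at ``z = 0``.

    Integer shifts only; voxels shifted past the top are replaced with
    the background mode, voxels below the substratum are discarded.
    """
    nz, ny, nx = vol.shape
    depth = sub.depth
    if depth.shape != (ny, nx):
        raise ValueError("substratum map does not match the volume grid")
    if depth.max() >= nz:
        raise ValueError("substratum depth exceeds the volume extent")
    bg = np.uint8(vol.background_mode())
    src_z = np.arange(nz)[:, None, None] + depth[None, :, :]
    valid = src_z < nz
    gathered = vol.data[
        np.minimum(src_z, nz - 1),
        np.arange(ny)[None, :, None],
        np.arange(nx)[None, None, :],
    ]
    out = np.where(valid, gathered, bg)
    return IntensityVolume(out.astype(np.uint8), vol.voxel_lateral, vol.voxel_axial)


def _projection(a) -> np.ndarray:
    if isinstance(a, (IntensityVolume, BinaryVolume)):
        return a.data.max(axis=0).astype(np.float64)
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 3:
        return a.max(axis=0)
    if a.ndim != 2:
        raise ValueError("expected a volume or a 2D map")
    return a


def register_pair(a, b, *, min_correlation: float = 0.2) -> tuple[int, int]:
    """Integer (dx, dy) shift of ``b`` relative to ``a``.

    Operates on 2D maximum-intensity projections and maximises their
    circular cross-correlation; ties break toward the smallest shift
    magnitude.  ``b ≈ roll(a, (dy, dx))`` at the returned shift.
    Featureless or uncorrelated pairs (normalised peak below
    ``min_correlation``) return (0, 0) with a warning.
    """
    pa = _projection(a)
    pb = _projection(b)
    if pa.shape != pb.shape:
        raise ValueError("inputs must share the same grid dimensions")
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    na = np.linalg.norm(pa)
    nb = np.linalg.norm(pb)
    if na == 0 or nb == 0:
        warnings.warn("featureless input; returning zero shift", stacklevel=2)
        return (0, 0)
    cc = np.fft.ifft2(np.fft.fft2(pb) * np.conj(np.fft.fft2(pa))).real
    peak = cc.max() / (na * nb)
    if peak < min_correlation:
        warnings.warn(
            f"registration peak correlation {peak:.3f} below {min_correlation}; "
            "returning zero shift",
            stacklevel=2,
        )
        return (0, 0)
    ny, nx = cc.shape
    candidates = np.argwhere(cc >= cc.max() - 1e-9 * abs(cc.max()))

    def signed(s: int, n: int) -> int:
        return int((s + n // 2) % n - n // 2)

    shifts = [(signed(sx, nx), signed(sy, ny)) for sy, sx in candidates]
    dx, dy = min(shifts, key=lambda s: (abs(s[0]) + abs(s[1]), abs(s[0]), abs(s[1])))
    return (dx, dy)
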