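"""Histogram-inflexion thresholding, binarisation and removal-only denoising.

The threshold is derived from the intensity histogram of the whole
stack: locate the mode (the background level), find the level right of
the mode that maximises the discrete second derivative of the (lightly
smoothed) histogram — the inflexion marking where biofilm signal starts
— and add a fixed offset of three intensity levels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .volume import BinaryVolume, IntensityVolume

THRESHOLD_OFFSET = 3
DEFAULT_OUTLIER_RADIUS = 2


class ThresholdResult(int):
    """The selected threshold, carrying the intermediate levels.

    Behaves as an ``int`` (the threshold itself) and exposes ``mode``
    and ``candidate`` attributes.
    """

    mode: int
    candidate: int

    def __new__(cls, threshold: int, mode: int, candidate: int) -> "ThresholdResult":
        obj = super().__new__(cls, threshold)
        obj.mode = int(mode)
        obj.candidate = int(candidate)
        return obj

    @property
    def threshold(self) -> int:
        return int(self)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ThresholdResult(threshold={int(self)}, mode={self.mode}, "
            f"candidate={self.candidate})"
        )


def compute_histogram(vol: IntensityVolume) -> np.ndarray:
    """Exact 256-bin intensity tally of the whole stack."""
    return np.bincount(vol.data.ravel(), minlength=256).astype(np.int64)


def _smooth(hist: np.ndarray) -> np.ndarray:
    # width-3 moving average; raw histograms of small volumes are jagged
    kernel = np.ones(3) / 3.0
    return np.convolve(hist, kernel, mode="same")


def find_threshold(
    hist: np.ndarray, *, smooth: bool = True, offset: int = THRESHOLD_OFFSET
) -> ThresholdResult:
    """Mode + second-derivative-inflexion threshold with a fixed offset.

    The candidate level maximises the central second difference
    ``h(i-1) - 2 h(i) + h(i+1)`` of the histogram strictly to the right
    of the mode; the returned threshold is ``candidate + offset``
    (capped at 255).  Ties — for the mode and for the candidate — break
    toward the lowest level.

    The candidate search starts far enough right of the mode that its
    stencil never touches the mode bin, which makes the threshold exactly
    invariant to padding the volume with background-level slices.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size != 256:
        raise ValueError("expected a 256-bin histogram")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    h = _smooth(hist) if smooth else hist
    # the mode comes from the raw tally; smoothing is only for the
    # second differences (it would smear a sharp mode across bins)
    mode = int(np.argmax(hist))
    # stencil of the second difference at i touches i-1 (and, smoothed,
    # i-2); keep both clear of the mode bin
    lo = mode + (3 if smooth else 2)
    hi = 254  # need i+1 <= 255
    if lo > hi:
        raise ValueError("no intensity levels to the right of the mode")
    i = np.arange(lo, hi + 1)
    d2 = h[i - 1] - 2.0 * h[i] + h[i + 1]
    candidate = int(i[np.argmax(d2)])
    threshold = min(candidate + offset, 255)
    return ThresholdResult(threshold, mode, candidate)


def binarise(vol: IntensityVolume, thr: int) -> BinaryVolume:
    """Strict binarisation: a voxel is biofilm when intensity > threshold."""
    thr = int(thr)
    if not 0 <= thr <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryVolume(vol.data > thr, vol.voxel_lateral, vol.voxel_axial)


def remove_outliers(
    bvol: BinaryVolume,
    radius: int = DEFAULT_OUTLIER_RADIUS,
    *,
    footprint: str = "disk",
) -> BinaryVolume:
    """Removal-only majority filter: clear sparse set voxels, never fill gaps.

    A set voxel is cleared when fewer than half of the voxels in its
    neighbourhood are set.  The default neighbourhood is a 2D disk of
    the given radius applied slice by slice (matching the in-plane
    salt-and-pepper character of the noise while sparing thin filaments);
    ``footprint="cube"`` uses a full 3D cube instead.  Out-of-volume
    neighbours count as unset.  The output is always a subset of the
    input.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if footprint == "disk":
        fp = disk(radius)[np.newaxis, :, :]
    elif footprint == "cube":
        side = 2 * radius + 1
        fp = np.ones((side, side, side), dtype=np.uint8)
    else:
        raise ValueError(f"unknown footprint {footprint!r}")
    counts = ndimage.convolve(
        bvol.data.astype(np.int32), fp.astype(np.int32), mode="constant", cval=0
    )
    keep = 2 * counts >= int(fp.sum())
    return BinaryVolume(bvol.data & keep, bvol.voxel_lateral, bvol.voxel_axial)


def trim_top(bvol: BinaryVolume, margin: int = 3) -> BinaryVolume:
    """Crop empty space above the biofilm, keeping ``margin`` spare slices.

    All set voxels are preserved.  An empty volume is cropped to a
    minimal stack of ``margin`` slices (at least one).
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    any_per_z = bvol.data.any(axis=(1, 2))
    if not any_per_z.any():
        new_nz = min(max(margin, 1), bvol.data.shape[0])
    else:
        top = int(np.nonzero(any_per_z)[0][-1])
        new_nz = min(top + 1 + margin, bvol.data.shape[0])
    return BinaryVolume(
        bvol.data[:new_nz].copy(), bvol.voxel_lateral, bvol.voxel_axial
    )
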