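"""Structural statistics of a binarised, flattened biofilm volume.

All maps use the top-face convention: a column whose highest set voxel
has index ``k`` has height ``(k + 1) * voxel_axial``.  Heights and
thicknesses are reported in micrometres; solidity (thickness over
height) is dimensionless and is computed from voxel counts so that the
streamer rule ``T/h <= 2/3`` is exact at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BinaryVolume

STREAMER_SOLIDITY_THRESHOLD = 2.0 / 3.0


@dataclass
class SurfaceMaps:
    """Per-column surface statistics.

    ``h`` and ``T`` are in micrometres; ``solidity`` is ``T/h`` (0 where
    the column is empty); ``streamer_mask`` marks occupied columns with
    ``solidity <= threshold``.
    """

    h: np.ndarray
    T: np.ndarray
    solidity: np.ndarray
    streamer_mask: np.ndarray


@dataclass(frozen=True)
class ScanSummary:
    """Scalar summary of one processed scan."""

    time: float  # h
    tau_w: float  # Pa
    SC: float  # substratum coverage, dimensionless
    V_b: float  # biovolume, um^3
    T_bar: float  # mean thickness, um
    field_area: float  # um^2

    def __post_init__(self) -> None:
        if not 0.0 <= self.SC <= 1.0:
            raise ValueError("SC must lie in [0, 1]")
        if self.field_area <= 0:
            raise ValueError("field_area must be positive")


def _top_index(bvol: BinaryVolume) -> np.ndarray:
    """Index of the highest set voxel per column; -1 for empty columns."""
    data = bvol.data
    nz = data.shape[0]
    occupied = data.any(axis=0)
    top = nz - 1 - np.argmax(data[::-1], axis=0)
    return np.where(occupied, top, -1)


def height_map(bvol: BinaryVolume) -> np.ndarray:
    """Biofilm height per column in um (includes enclosed voids)."""
    return (_top_index(bvol) + 1) * bvol.voxel_axial


def thickness_map(bvol: BinaryVolume) -> np.ndarray:
    """Biofilm thickness per column in um (excludes voids)."""
    return bvol.data.sum(axis=0) * bvol.voxel_axial


def solidity_map(h: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Solidity ``T/h``; defined as 0 where ``h = 0``.

    Works on any consistent pair of maps (um or voxel counts).  Columns
    with ``h = 0`` carry no biofilm and are excluded from streamer/base
    classification.
    """
    h = np.asarray(h, dtype=float)
    T = np.asarray(T, dtype=float)
    if h.shape != T.shape:
        raise ValueError("maps must share a grid")
    out = np.zeros_like(h)
    np.divide(T, h, out=out, where=h > 0)
    return out


def classify_streamers(
    solidity: np.ndarray, threshold: float = STREAMER_SOLIDITY_THRESHOLD
) -> np.ndarray:
    """Columns classified as streamer: occupied and ``T/h <= threshold``.

    The rule is inclusive at the threshold.  Empty columns
    (``solidity == 0`` because ``h == 0``) belong to neither class.
    """
    solidity = np.asarray(solidity)
    return (solidity > 0) & (solidity <= threshold)


def compute_surface_maps(
    bvol: BinaryVolume, threshold: float = STREAMER_SOLIDITY_THRESHOLD
) -> SurfaceMaps:
    """Height, thickness, solidity and streamer mask in one pass.

    Solidity is formed from integer voxel counts, so ratios such as 2/3
    compare exactly against the default threshold.
    """
    top = _top_index(bvol)
    h_vox = top + 1
    t_vox = bvol.data.sum(axis=0)
    solidity = solidity_map(h_vox, t_vox)
    return SurfaceMaps(
        h=h_vox * bvol.voxel_axial,
        T=t_vox * bvol.voxel_axial,
        solidity=solidity,
        streamer_mask=classify_streamers(solidity, threshold),
    )


def substratum_coverage(bvol: BinaryVolume, variant: str = "bottom-layer") -> float:
    """Fraction of the substratum covered by biofilm.

    ``"bottom-layer"`` counts columns with a set voxel in the layer
    directly on the substratum (``z = 0``); ``"max-projection"`` counts
    columns with a set voxel anywhere (the definition used by some
    earlier work), and is always >= the bottom-layer value.
    """
    if variant == "bottom-layer":
        return float(bvol.data[0].mean())
    if variant == "max-projection":
        return float(bvol.data.any(axis=0).mean())
    raise ValueError(f"unknown variant {variant!r}")


def biovolume(bvol: BinaryVolume) -> float:
    """Total biofilm volume in um^3 (set voxels times voxel volume)."""
    return bvol.count() * bvol.voxel_volume


def mean_thickness(bvol: BinaryVolume, A: float | None = None) -> float:
    """Mean biofilm thickness ``T_bar = V_b / A`` in um.

    ``A`` defaults to the full lateral field area of the volume.
    """
    if A is None:
        ny, nx = bvol.data.shape[1:]
        A = ny * nx * bvol.voxel_lateral**2
    if A <= 0:
        raise ValueError("field area must be positive")
    return biovolume(bvol) / A


def summarize_scan(
    bvol: BinaryVolume,
    time: float,
    tau_w: float,
    *,
    A: float | None = None,
    sc_variant: str = "bottom-layer",
) -> ScanSummary:
    """Bundle coverage, biovolume and mean thickness for one scan."""
    if A is None:
        ny, nx = bvol.data.shape[1:]
        A = ny * nx * bvol.voxel_lateral**2
    return ScanSummary(
        time=time,
        tau_w=tau_w,
        SC=substratum_coverage(bvol, sc_variant),
        V_b=biovolume(bvol),
        T_bar=biovolume(bvol) / A,
        field_area=A,
    )


def label_structures(bvol: BinaryVolume):
    """Connected-component labelling utility (26-connectivity).

    Provided for exploratory use; none of the reported statistics
    require component grouping.
    """
    from scipy import ndimage

    labels, n = ndimage.label(bvol.data, structure=np.ones((3, 3, 3), dtype=bool))
    return labels, n
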