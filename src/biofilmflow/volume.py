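"""Volume containers shared by every stage of the pipeline.

Volumes are indexed ``[z][y][x]`` with ``z`` increasing away from the
physical bottom of the scan.  Intensities live on an 8-bit (0-255) scale;
binarised volumes carry the voxel sizes of their source scan so that all
morphometric statistics can be reported in physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: default lateral voxel pitch of the scans, micrometres
DEFAULT_VOXEL_LATERAL = 12.0
#: default axial voxel pitch (in water), micrometres
DEFAULT_VOXEL_AXIAL = 2.1


def quantise_intensity(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half-up to an unsigned 8-bit grid."""
    return np.floor(np.clip(values, 0.0, 255.0) + 0.5).clip(0, 255).astype(np.uint8)


def _check_voxels(lateral: float, axial: float) -> None:
    if lateral <= 0 or axial <= 0:
        raise ValueError("voxel sizes must be positive")


@dataclass
class IntensityVolume:
    """A 3D greyscale scan on a regular voxel grid.

    Parameters
    ----------
    data
        ``uint8`` array of shape ``(nz, ny, nx)``.
    voxel_lateral
        In-plane voxel pitch in micrometres (x and y).
    voxel_axial
        Axial voxel pitch in micrometres (z).
    """

    data: np.ndarray
    voxel_lateral: float = DEFAULT_VOXEL_LATERAL
    voxel_axial: float = DEFAULT_VOXEL_AXIAL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("intensity data must be a non-empty 3D array")
        if self.data.dtype != np.uint8:
            if not np.issubdtype(self.data.dtype, np.integer):
                raise TypeError("intensity data must be integer-valued (0-255)")
            if self.data.min() < 0 or self.data.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.data = self.data.astype(np.uint8)
        _check_voxels(self.voxel_lateral, self.voxel_axial)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nz(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nx(self) -> int:
        return self.data.shape[2]

    def background_mode(self) -> int:
        """Most frequent intensity level; ties break toward the lowest level."""
        counts = np.bincount(self.data.ravel(), minlength=256)
        return int(np.argmax(counts))

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.data.copy(), self.voxel_lateral, self.voxel_axial)


@dataclass
class BinaryVolume:
    """Binarised biofilm indicator on the grid of its source scan.

    After flattening, ``z = 0`` is the substratum layer; the morphometrics
    stage expects the substratum itself to have been stripped so that
    ``z = 0`` is the first biofilm-bearing layer.
    """

    data: np.ndarray
    voxel_lateral: float = DEFAULT_VOXEL_LATERAL
    voxel_axial: float = DEFAULT_VOXEL_AXIAL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("binary data must be a non-empty 3D array")
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary volume may only contain 0/1")
            self.data = self.data.astype(bool)
        _check_voxels(self.voxel_lateral, self.voxel_axial)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return self.voxel_lateral**2 * self.voxel_axial

    def count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(self.data.copy(), self.voxel_lateral, self.voxel_axial)


# ---------------------------------------------------------------------------
# TIFF I/O.  Multi-page TIFF, one page per z-slice, plus a JSON sidecar
# carrying the voxel sizes (TIFF has no standard slot for an axial pitch).
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(vol: IntensityVolume | BinaryVolume, path: str | Path) -> None:
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(path, data)
    meta = {
        "voxel_lateral_um": vol.voxel_lateral,
        "voxel_axial_um": vol.voxel_axial,
        "binary": isinstance(vol, BinaryVolume),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_volume(path: str | Path) -> IntensityVolume | BinaryVolume:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    lateral = float(meta.get("voxel_lateral_um", DEFAULT_VOXEL_LATERAL))
    axial = float(meta.get("voxel_axial_um", DEFAULT_VOXEL_AXIAL))
    if meta.get("binary", False):
        return BinaryVolume(data > 0, lateral, axial)
    return IntensityVolume(data.astype(np.uint8), lateral, axial)
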