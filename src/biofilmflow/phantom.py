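"""Synthetic scan generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:
Gaussian background noise, a bright (optionally tilted) substratum
plane, leaning-pillar microcolonies with rounded caps, and thin
horizontal streamer filaments attached at the colony tip with empty
voxels beneath them.  Time series of such volumes follow the
erosion-growth balance of :mod:`biofilmflow.growth_model`, with colonies
appearing as a homogeneous Poisson process.

Ground truth lives in a substratum-relative frame: layer ``k = 0`` of
:class:`PhantomGroundTruth.true_binary` is the first voxel layer above
the substratum plane.  All randomness flows from a single integer seed
through :class:`numpy.random.SeedSequence` spawning (one child per scan,
plus one each for arrival times and colony placement).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .growth_model import (
    GrowthParams,
    closed_form_height,
    equilibrium_height,
)
from .volume import (
    DEFAULT_VOXEL_AXIAL,
    DEFAULT_VOXEL_LATERAL,
    BinaryVolume,
    IntensityVolume,
    quantise_intensity,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian background noise on the 0-255 intensity scale."""

    mean_level: float = 30.0
    sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.mean_level <= 255:
            raise ValueError("mean_level must lie in [0, 255]")


@dataclass(frozen=True)
class ColonySpec:
    """Geometry and intensity of one microcolony.

    The base is a pillar with a circular footprint whose axis leans
    downstream (+x) by ``lean_angle`` degrees from vertical, topped by a
    rounded cap.  If ``streamer_length > 0`` a horizontal filament of
    square cross-section ``streamer_thickness`` extends downstream from
    the tip, with background left untouched beneath it.
    """

    footprint_centre: tuple[float, float]  # (x, y) voxels
    footprint_radius: int
    height: int
    lean_angle: float = 0.0  # degrees from vertical, toward +x
    streamer_length: int = 0
    streamer_thickness: int = 3
    biofilm_intensity_mean: float = 90.0
    biofilm_intensity_sigma: float = 8.0

    def __post_init__(self) -> None:
        if self.footprint_radius < 1:
            raise ValueError("footprint_radius must be >= 1")
        if self.height < 1:
            raise ValueError("height must be >= 1")
        if self.streamer_length < 0 or self.streamer_thickness < 1:
            raise ValueError("invalid streamer geometry")


@dataclass
class PhantomGroundTruth:
    """Exact voxel-level truth for one synthetic scan.

    ``true_binary`` is defined on the substratum-relative grid
    (``k = 0`` directly above the plane).  ``true_footprint_area`` is the
    number of columns covered at ``k = 0`` (multiply by the lateral voxel
    area for um^2).
    """

    true_binary: BinaryVolume
    true_height_map: np.ndarray
    true_footprint_area: int
    colony_table: list[ColonySpec] = field(default_factory=list)

    @classmethod
    def empty(
        cls,
        shape: tuple[int, int, int],
        voxel_lateral: float = DEFAULT_VOXEL_LATERAL,
        voxel_axial: float = DEFAULT_VOXEL_AXIAL,
    ) -> "PhantomGroundTruth":
        nz, ny, nx = shape
        return cls(
            true_binary=BinaryVolume(
                np.zeros((nz, ny, nx), dtype=bool), voxel_lateral, voxel_axial
            ),
            true_height_map=np.zeros((ny, nx), dtype=np.int64),
            true_footprint_area=0,
        )

    def mean_thickness(self) -> float:
        """Ground-truth mean biofilm thickness in um."""
        b = self.true_binary
        ny, nx = b.data.shape[1:]
        return b.count() * b.voxel_axial / (ny * nx)


def make_noise_volume(
    shape: tuple[int, int, int],
    noise: NoiseSpec,
    *,
    voxel_lateral: float = DEFAULT_VOXEL_LATERAL,
    voxel_axial: float = DEFAULT_VOXEL_AXIAL,
    quantise: bool = True,
    rng: np.random.Generator | None = None,
) -> IntensityVolume | np.ndarray:
    """Pure-noise volume: i.i.d. Gaussian intensities, clipped and quantised.

    With ``quantise=False`` the raw float draws are returned (useful for
    testing tail statistics without discretisation effects).
    """
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError("shape must be a positive (nz, ny, nx) triple")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    raw = rng.normal(noise.mean_level, noise.sigma, size=tuple(shape))
    if not quantise:
        return raw
    return IntensityVolume(quantise_intensity(raw), voxel_lateral, voxel_axial)


def substratum_depth_map(
    shape_yx: tuple[int, int],
    tilt_deg: float,
    base_depth: int,
    voxel_lateral: float,
    voxel_axial: float,
) -> np.ndarray:
    """Integer substratum depth per column for a plane tilted about y.

    Depth increases linearly with x at a slope of
    ``tan(tilt) * voxel_lateral / voxel_axial`` axial voxels per lateral
    voxel.
    """
    ny, nx = shape_yx
    slope = math.tan(math.radians(tilt_deg)) * voxel_lateral / voxel_axial
    depth_x = np.floor(base_depth + slope * np.arange(nx) + 0.5).astype(np.int64)
    return np.broadcast_to(depth_x, (ny, nx)).copy()


def add_substratum(
    vol: IntensityVolume,
    tilt_deg: float,
    brightness: int = 255,
    base_depth: int = 2,
) -> tuple[IntensityVolume, np.ndarray]:
    """Insert a bright substratum plane; returns (volume, true depth map).

    The plane is one voxel thick and is the brightest voxel of each
    column by construction when ``brightness`` exceeds the noise range.
    """
    depth = substratum_depth_map(
        (vol.ny, vol.nx), tilt_deg, base_depth, vol.voxel_lateral, vol.voxel_axial
    )
    if depth.min() < 0 or depth.max() >= vol.nz:
        raise ValueError("substratum plane exits the volume; reduce tilt or base depth")
    out = vol.copy()
    yy, xx = np.meshgrid(np.arange(vol.ny), np.arange(vol.nx), indexing="ij")
    out.data[depth, yy, xx] = np.uint8(brightness)
    return out, depth


def _colony_level_radius(colony: ColonySpec, k: int) -> float:
    """Footprint radius of the pillar at level ``k`` (rounded cap on top)."""
    r = float(colony.footprint_radius)
    cap = max(1, colony.height // 4) if colony.height >= 4 else 0
    k_cap = colony.height - 1 - cap
    if cap == 0 or k <= k_cap:
        return r
    u = (k - k_cap) / (cap + 0.5)
    return r * math.sqrt(max(0.0, 1.0 - u * u))


def _colony_voxels(
    colony: ColonySpec, shape_yx: tuple[int, int], voxel_lateral: float, voxel_axial: float
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Per-level (k, ys, xs) voxel coordinates of base + streamer.

    Raises ``ValueError`` if any voxel would fall outside the lateral
    field.  Coordinates are substratum-relative levels ``k >= 0``.
    """
    ny, nx = shape_yx
    cx, cy = colony.footprint_centre
    lean_slope = (
        math.tan(math.radians(colony.lean_angle)) * voxel_axial / voxel_lateral
    )
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    levels: list[tuple[int, np.ndarray, np.ndarray]] = []
    for k in range(colony.height):
        rk = _colony_level_radius(colony, k)
        cxk = cx + lean_slope * k
        if cxk - rk < -0.5 or cxk + rk > nx - 0.5 or cy - rk < -0.5 or cy + rk > ny - 0.5:
            raise ValueError("colony out of lateral bounds")
        mask = (xx - cxk) ** 2 + (yy - cy) ** 2 <= rk**2 + 1e-9
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            # always keep at least the axis voxel so the tip is defined
            ys = np.array([int(round(cy))])
            xs = np.array([int(round(cxk))])
        levels.append((k, ys, xs))
    if colony.streamer_length > 0:
        th = colony.streamer_thickness
        tip_k = colony.height - 1
        tip_x = cx + lean_slope * tip_k
        x0 = int(round(tip_x)) + 1
        x1 = x0 + colony.streamer_length  # exclusive
        y0 = int(round(cy)) - th // 2
        y1 = y0 + th
        k_lo = max(0, tip_k - th + 1)
        if x1 > nx or x0 < 0 or y0 < 0 or y1 > ny:
            raise ValueError("streamer out of lateral bounds")
        ys_s, xs_s = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
        for k in range(k_lo, tip_k + 1):
            levels.append((k, ys_s.ravel(), xs_s.ravel()))
    return levels


def add_colony(
    vol: IntensityVolume,
    colony: ColonySpec,
    noise: NoiseSpec,
    substratum_depth: np.ndarray | int = -1,
    truth: PhantomGroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityVolume, PhantomGroundTruth]:
    """Paint one microcolony into ``vol`` and update the ground truth.

    ``substratum_depth`` is the per-column z-index of the substratum
    plane (or a scalar; ``-1`` places colony bases at ``z = 0`` when no
    plane exists).  Colony voxels receive Gaussian intensities around
    ``biofilm_intensity_mean``; background beneath streamers is left
    untouched.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    ny, nx = vol.ny, vol.nx
    depth = np.broadcast_to(np.asarray(substratum_depth, dtype=np.int64), (ny, nx))
    if truth is None:
        truth = PhantomGroundTruth.empty(vol.shape, vol.voxel_lateral, vol.voxel_axial)
    out = vol.copy()
    levels = _colony_voxels(colony, (ny, nx), vol.voxel_lateral, vol.voxel_axial)
    # bounds check along z before mutating anything
    for k, ys, xs in levels:
        if np.any(depth[ys, xs] + 1 + k >= vol.nz):
            raise ValueError("colony out of vertical bounds")
    for k, ys, xs in levels:
        zs = depth[ys, xs] + 1 + k
        vals = quantise_intensity(
            rng.normal(
                colony.biofilm_intensity_mean,
                colony.biofilm_intensity_sigma,
                size=len(ys),
            )
        )
        out.data[zs, ys, xs] = vals
        truth.true_binary.data[k, ys, xs] = True
        truth.true_height_map[ys, xs] = np.maximum(truth.true_height_map[ys, xs], k + 1)
    truth.true_footprint_area = int(truth.true_binary.data[0].sum())
    truth.colony_table.append(colony)
    return out, truth


@dataclass(frozen=True)
class TimeSeriesSpec:
    """Specification of a synthetic growth time series at one shear level."""

    growth_params: GrowthParams
    tau_w: float  # Pa
    times: tuple[float, ...]  # hours, strictly increasing
    shape: tuple[int, int, int] = (80, 96, 96)  # (nz, ny, nx)
    noise: NoiseSpec = NoiseSpec()
    tilt_deg: float = 2.0
    substratum_brightness: int = 200
    base_depth: int = 2
    lean_angle: float = 15.0
    biofilm_intensity_mean: float = 90.0
    biofilm_intensity_sigma: float = 8.0
    streamer_onset_fraction: float = 0.9
    streamer_length: int = 15
    streamer_thickness: int = 3
    voxel_lateral: float = DEFAULT_VOXEL_LATERAL
    voxel_axial: float = DEFAULT_VOXEL_AXIAL
    seed: int = 0
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")
        times = tuple(float(t) for t in self.times)
        if len(times) == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def field_area(self) -> float:
        """Lateral field-of-view area in um^2."""
        _, ny, nx = self.shape
        return ny * nx * self.voxel_lateral**2


def sample_arrivals(
    beta: float, t_max: float, rng: np.random.Generator
) -> np.ndarray:
    """Birth times of a homogeneous Poisson process of rate ``beta`` on [0, t_max]."""
    if beta < 0 or t_max < 0:
        raise ValueError("beta and t_max must be non-negative")
    n = rng.poisson(beta * t_max)
    return np.sort(rng.uniform(0.0, t_max, size=n))


def _place_colonies(
    n: int,
    r_vox: int,
    shape_yx: tuple[int, int],
    x_margin_hi: int,
    rng: np.random.Generator,
    max_attempts: int,
) -> list[tuple[float, float]]:
    """Uniform placement with overlap rejection; skips unplaceable colonies."""
    ny, nx = shape_yx
    lo = r_vox + 2
    hi_x = nx - 1 - x_margin_hi
    hi_y = ny - 1 - (r_vox + 2)
    if hi_x <= lo or hi_y <= lo:
        raise ValueError("field too small for the requested colony radius")
    centres: list[tuple[float, float]] = []
    min_sep2 = (2 * r_vox + 2) ** 2
    skipped = 0
    for _ in range(n):
        for _attempt in range(max_attempts):
            cx = rng.uniform(lo, hi_x)
            cy = rng.uniform(lo, hi_y)
            if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep2 for px, py in centres):
                centres.append((cx, cy))
                break
        else:
            skipped += 1
    if skipped:
        warnings.warn(
            f"could not place {skipped}/{n} colonies without overlap "
            f"after {max_attempts} attempts each; they were skipped",
            stacklevel=2,
        )
    return centres


def generate_time_series(
    spec: TimeSeriesSpec,
) -> list[tuple[float, IntensityVolume, PhantomGroundTruth]]:
    """Synthetic growth series: list of (time, volume, ground truth).

    Colonies appear as a Poisson process at rate ``beta``; each colony's
    height follows the deterministic erosion-growth solution from its
    birth time, saturating at ``h_max``.  A streamer is attached once the
    base exceeds ``streamer_onset_fraction * h_max`` (clipped to the
    field edge if needed).  Deterministic for a fixed spec and seed.
    """
    p = spec.growth_params
    nz, ny, nx = spec.shape
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + len(spec.times))
    rng_arrival = np.random.default_rng(children[0])
    rng_place = np.random.default_rng(children[1])

    t_max = spec.times[-1]
    births = sample_arrivals(p.beta, t_max, rng_arrival)

    r_vox = max(1, int(round(math.sqrt(p.A_fp / math.pi) / spec.voxel_lateral)))
    h_max_um = equilibrium_height(p, spec.tau_w)
    h_max_vox = max(1, int(math.floor(h_max_um / spec.voxel_axial)))
    lean_slope = (
        math.tan(math.radians(spec.lean_angle)) * spec.voxel_axial / spec.voxel_lateral
    )
    x_margin_hi = r_vox + 2 + int(math.ceil(lean_slope * h_max_vox))

    depth = substratum_depth_map(
        (ny, nx), spec.tilt_deg, spec.base_depth, spec.voxel_lateral, spec.voxel_axial
    )
    if depth.max() + 1 + h_max_vox + 1 >= nz:
        raise ValueError(
            "volume too shallow: substratum depth + equilibrium colony height "
            f"needs at least {depth.max() + h_max_vox + 3} z-voxels (have {nz})"
        )

    centres = _place_colonies(
        len(births), r_vox, (ny, nx), x_margin_hi, rng_place, spec.max_place_attempts
    )
    births = births[: len(centres)]

    series: list[tuple[float, IntensityVolume, PhantomGroundTruth]] = []
    for i, t in enumerate(spec.times):
        rng_scan = np.random.default_rng(children[2 + i])
        noise = spec.noise
        vol = make_noise_volume(
            (nz, ny, nx),
            noise,
            voxel_lateral=spec.voxel_lateral,
            voxel_axial=spec.voxel_axial,
            rng=rng_scan,
        )
        vol, _ = add_substratum(
            vol, spec.tilt_deg, spec.substratum_brightness, spec.base_depth
        )
        truth = PhantomGroundTruth.empty(
            (nz, ny, nx), spec.voxel_lateral, spec.voxel_axial
        )
        for birth, (cx, cy) in zip(births, centres):
            if birth >= t:
                continue
            h_um = float(closed_form_height(p, spec.tau_w, t - birth))
            h_vox = int(round(h_um / spec.voxel_axial))
            if h_vox < 1:
                continue
            streamer_len = 0
            if h_um >= spec.streamer_onset_fraction * h_max_um and spec.streamer_length:
                tip_x = int(round(cx + lean_slope * (h_vox - 1))) + 1
                streamer_len = min(spec.streamer_length, nx - tip_x)
                streamer_len = max(0, streamer_len)
            colony = ColonySpec(
                footprint_centre=(cx, cy),
                footprint_radius=r_vox,
                height=h_vox,
                lean_angle=spec.lean_angle,
                streamer_length=streamer_len,
                streamer_thickness=spec.streamer_thickness,
                biofilm_intensity_mean=spec.biofilm_intensity_mean,
                biofilm_intensity_sigma=spec.biofilm_intensity_sigma,
            )
            vol, truth = add_colony(vol, colony, noise, depth, truth, rng=rng_scan)
        series.append((t, vol, truth))
    return series
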