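"""End-to-end orchestration: phantom -> preprocess -> segment -> quantify -> fit.

Stages follow the order of the reference processing chain: rotate,
align the substratum with the bottom of the scan, binarise, denoise,
trim, then quantify.  After flattening, the substratum layer itself is
dropped and a lateral margin (defaulting to the median-filter radius) is
cropped before thresholding, so edge artefacts of the substratum
detection cannot leak into the histogram or the statistics; the
field-of-view area used for normalisation is the cropped one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import morphometrics, preprocess, segmentation
from .growth_model import GrowthParams, PowerLawFit, recover_from_pipeline
from .morphometrics import ScanSummary
from .phantom import NoiseSpec, TimeSeriesSpec, generate_time_series
from .volume import BinaryVolume, IntensityVolume, save_volume

log = logging.getLogger("biofilmflow")


@dataclass(frozen=True)
class SegmentationOptions:
    smooth: bool = True
    offset: int = segmentation.THRESHOLD_OFFSET
    denoise: bool = True
    outlier_radius: int = segmentation.DEFAULT_OUTLIER_RADIUS
    outlier_footprint: str = "disk"
    trim_margin: int = 3


@dataclass(frozen=True)
class QuantifyOptions:
    drop_bottom_layers: int = 1
    edge_crop: int = preprocess.DEFAULT_MEDIAN_RADIUS + 1
    sc_variant: str = "bottom-layer"
    streamer_threshold: float = morphometrics.STREAMER_SOLIDITY_THRESHOLD


def process_volume(
    vol: IntensityVolume,
    *,
    time: float = 0.0,
    tau_w: float = 1.0,
    rotate_angles: tuple[float, float] = (0.0, 0.0),
    seg: SegmentationOptions = SegmentationOptions(),
    quant: QuantifyOptions = QuantifyOptions(),
) -> tuple[ScanSummary, dict[str, Any], BinaryVolume]:
    """Run one scan through the full measurement chain.

    Returns the scan summary, a JSON-serialisable stage report, and the
    final trimmed binary volume.
    """
    report: dict[str, Any] = {"time": time, "tau_w": tau_w}
    t0 = _time.perf_counter()

    if rotate_angles != (0.0, 0.0):
        vol = preprocess.rotate_volume(vol, *rotate_angles)
        report["rotated_by"] = list(rotate_angles)

    sub = preprocess.detect_substratum(vol)
    report["substratum"] = {
        "median_depth": float(np.median(sub.depth)),
        "low_confidence": sub.low_confidence,
        "outlier_fraction": sub.outlier_fraction,
    }
    flat = preprocess.flatten(vol, sub)

    z0 = quant.drop_bottom_layers
    if z0 >= flat.nz:
        raise ValueError("drop_bottom_layers leaves no volume")
    c = quant.edge_crop
    if 2 * c >= min(flat.ny, flat.nx):
        raise ValueError("edge_crop leaves no field of view")
    data = flat.data[z0:, c : flat.ny - c or None, c : flat.nx - c or None]
    cropped = IntensityVolume(data.copy(), vol.voxel_lateral, vol.voxel_axial)

    hist = segmentation.compute_histogram(cropped)
    thr = segmentation.find_threshold(hist, smooth=seg.smooth, offset=seg.offset)
    report["threshold"] = {
        "mode": thr.mode,
        "candidate": thr.candidate,
        "threshold": int(thr),
    }
    binary = segmentation.binarise(cropped, thr)
    report["voxels_above_threshold"] = binary.count()

    if seg.denoise:
        binary = segmentation.remove_outliers(
            binary, seg.outlier_radius, footprint=seg.outlier_footprint
        )
        report["voxels_after_denoise"] = binary.count()

    binary = segmentation.trim_top(binary, seg.trim_margin)
    report["trimmed_z_extent"] = binary.data.shape[0]

    summary = morphometrics.summarize_scan(
        binary, time, tau_w, sc_variant=quant.sc_variant
    )
    report["summary"] = dataclasses.asdict(summary)
    report["elapsed_s"] = round(_time.perf_counter() - t0, 3)
    log.info(
        "processed scan t=%.1f h tau_w=%.3g Pa: threshold=%d, SC=%.4f, T_bar=%.3f um",
        time,
        tau_w,
        int(thr),
        summary.SC,
        summary.T_bar,
    )
    return summary, report, binary


@dataclass
class RunConfig:
    """Configuration of a full synthetic-data pipeline run."""

    seed: int = 0
    tau_w: tuple[float, ...] = (0.068, 0.67)
    times: tuple[float, ...] = (24.0, 48.0, 72.0)
    shape: tuple[int, int, int] = (80, 96, 96)
    noise_mean: float = 30.0
    noise_sigma: float = 5.0
    tilt_deg: float = 2.0
    substratum_brightness: int = 200
    base_depth: int = 2
    growth: dict[str, float] = field(
        default_factory=lambda: {
            "g": 22.0,
            "C": 1.0,
            "mu_b_pa_s": 1000.0,
            "beta": 0.08,
            "A_fp": 22000.0,
        }
    )
    lean_angle: float = 15.0
    streamer_length: int = 15
    streamer_thickness: int = 3
    biofilm_intensity_mean: float = 90.0
    biofilm_intensity_sigma: float = 8.0
    segmentation: SegmentationOptions = field(default_factory=SegmentationOptions)
    quantify: QuantifyOptions = field(default_factory=QuantifyOptions)
    n_replicates: int = 1
    fit: bool = True
    out_dir: str | None = None
    save_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            value = raw[f.name]
            if f.name == "segmentation":
                value = SegmentationOptions(**value)
            elif f.name == "quantify":
                value = QuantifyOptions(**value)
            elif f.name in ("tau_w", "times"):
                value = tuple(value)
            elif f.name == "shape":
                value = tuple(int(v) for v in value)
            kwargs[f.name] = value
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def growth_params(self) -> GrowthParams:
        nz, ny, nx = self.shape
        from .volume import DEFAULT_VOXEL_LATERAL

        area = ny * nx * DEFAULT_VOXEL_LATERAL**2
        g = self.growth
        return GrowthParams.with_si_viscosity(
            g=g["g"],
            C=g["C"],
            mu_b_pa_s=g["mu_b_pa_s"],
            beta=g["beta"],
            A_fp=g["A_fp"],
            A=area,
        )


@dataclass
class PipelineResult:
    summaries: pd.DataFrame
    fit: PowerLawFit | None
    reports: list[dict[str, Any]]
    scan_summaries: list[ScanSummary]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Generate phantom series at each shear level, measure, and fit.

    Fully deterministic for a fixed config (the seed feeds every source
    of randomness).  When ``config.out_dir`` is set, writes
    ``summaries.csv``, per-scan JSON reports, the fit report and the
    effective config.
    """
    params = config.growth_params()
    all_summaries: list[ScanSummary] = []
    reports: list[dict[str, Any]] = []
    binaries: list[tuple[str, BinaryVolume]] = []

    conditions = [
        (i, tau, rep)
        for i, tau in enumerate(config.tau_w)
        for rep in range(config.n_replicates)
    ]
    for i, tau, rep in conditions:
        spec = TimeSeriesSpec(
            growth_params=params,
            tau_w=tau,
            times=config.times,
            shape=config.shape,
            noise=NoiseSpec(config.noise_mean, config.noise_sigma, config.seed),
            tilt_deg=config.tilt_deg,
            substratum_brightness=config.substratum_brightness,
            base_depth=config.base_depth,
            lean_angle=config.lean_angle,
            biofilm_intensity_mean=config.biofilm_intensity_mean,
            biofilm_intensity_sigma=config.biofilm_intensity_sigma,
            streamer_length=config.streamer_length,
            streamer_thickness=config.streamer_thickness,
            seed=config.seed + 7919 * i + 104729 * rep,
        )
        log.info(
            "generating series at tau_w=%.3g Pa (replicate %d/%d)",
            tau,
            rep + 1,
            config.n_replicates,
        )
        for t, vol, _truth in generate_time_series(spec):
            summary, report, binary = process_volume(
                vol,
                time=t,
                tau_w=tau,
                seg=config.segmentation,
                quant=config.quantify,
            )
            all_summaries.append(summary)
            reports.append(report)
            if config.save_volumes:
                binaries.append((f"binary_tau{tau:g}_r{rep}_t{t:g}.tif", binary))

    df = pd.DataFrame(
        {
            "t": [s.time for s in all_summaries],
            "tau_w": [s.tau_w for s in all_summaries],
            "SC": [s.SC for s in all_summaries],
            "V_b": [s.V_b for s in all_summaries],
            "T_bar": [s.T_bar for s in all_summaries],
        }
    )

    fit_result: PowerLawFit | None = None
    if config.fit and len(set(config.tau_w)) >= 2:
        try:
            fit_result = recover_from_pipeline(all_summaries)
            log.info(
                "power-law fit: a=%.4g +/- %.2g, k=%.4g +/- %.2g",
                fit_result.a,
                fit_result.a_sd,
                fit_result.k,
                fit_result.k_sd,
            )
        except ValueError as exc:
            log.warning("power-law fit failed: %s", exc)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "summaries.csv", index=False)
        (out / "reports").mkdir(exist_ok=True)
        for j, report in enumerate(reports):
            (out / "reports" / f"scan_{j:03d}.json").write_text(
                json.dumps(report, indent=2)
            )
        if fit_result is not None:
            (out / "fit.json").write_text(
                json.dumps(dataclasses.asdict(fit_result), indent=2)
            )
        cfg = dataclasses.asdict(config)
        (out / "config_used.json").write_text(json.dumps(cfg, indent=2, default=str))
        for name, binary in binaries:
            save_volume(binary, out / name)

    return PipelineResult(
        summaries=df, fit=fit_result, reports=reports, scan_summaries=all_summaries
    )
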