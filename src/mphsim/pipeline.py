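"""End-to-end case orchestration: register -> calibrate -> segment ->
build -> solve -> summarize -> dose, driven by one YAML case configuration.

Each stage is a plain function taking explicit inputs, so stages are
individually invocable with results identical to the orchestrated run;
:func:`run_case` just composes them, logs provenance (config hash, package
version, stage order) and converts any stage failure into a
:class:`StageError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import yaml

from . import __version__
from .calibration import (
    CalibrationCurve,
    fit_calibration,
    gv_to_power,
    read_calibration_csv,
)
from .dosimetry import cem43, cem43_from_summary
from .imaging_io import (
    VoxelImage,
    read_image,
    read_landmarks,
    read_timeseries,
)
from .phantom import (
    Mask,
    Phantom,
    build_phantom,
    default_materials,
    threshold_segment,
    total_source_power,
)
from .physics import (
    BoundaryConditions,
    CoilDrive,
    HeatingSchedule,
    TemperatureSeries,
    solve_transient,
)
from .registration import AffineTransform, estimate_transform, resample

__all__ = ["CaseConfig", "StageError", "run_case"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CaseConfig:
    """Validated view of a case YAML file; paths resolve against base_dir."""

    raw: dict
    base_dir: Path

    REQUIRED = ("paths", "segmentation", "phantom", "coil", "solver", "schedules")

    def __post_init__(self) -> None:
        missing = [k for k in self.REQUIRED if k not in self.raw]
        if missing:
            raise ValueError(f"case config missing sections: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        path = Path(path)
        return cls(yaml.safe_load(path.read_text()), path.parent)

    def path(self, key: str) -> Path:
        p = Path(self.raw["paths"][key])
        return p if p.is_absolute() else self.base_dir / p

    def section(self, name: str, default: dict | None = None) -> dict:
        return self.raw.get(name, default if default is not None else {})

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CaseResult:
    """Everything :func:`run_case` produced, plus where it was written."""

    transform: AffineTransform
    curve: CalibrationCurve
    phantom: Phantom
    series: dict[str, TemperatureSeries]
    doses: dict[str, dict[str, float]]
    output_dir: Path
    log: dict = field(default_factory=dict)


# ---- stages ------------------------------------------------------------


def stage_register(config: CaseConfig):
    """Estimate the fiducial transform and resample the tracer image."""
    fixed = read_landmarks(config.path("landmarks_fixed"))
    moving = read_landmarks(config.path("landmarks_moving"))
    model = config.section("registration").get("model", "similarity")
    transform = estimate_transform(fixed, moving, model=model)
    tracer = read_image(config.path("tracer"))
    anatomical = read_image(config.path("anatomical"))
    registered = resample(tracer, transform, anatomical, interpolation="trilinear")
    return transform, anatomical, registered


def stage_calibrate(config: CaseConfig, registered: VoxelImage):
    """Fit the GV/power calibration and convert the registered tracer."""
    cal_path = config.path("calibration")
    if not cal_path.exists():
        raise FileNotFoundError(f"calibration table not found: {cal_path}")
    slp = float(config.section("calibration").get("slp", 496.0))
    curve = fit_calibration(read_calibration_csv(cal_path), slp=slp)
    power = gv_to_power(registered, curve)
    return curve, power


def stage_segment(config: CaseConfig, anatomical: VoxelImage, registered: VoxelImage,
                  power: VoxelImage):
    """Tumor and tracer masks; restrict the source field to the tumor ROI."""
    from scipy import ndimage

    seg = config.section("segmentation")
    tumor_mask = threshold_segment(
        anatomical, float(seg["tumor_lower"]), float(seg["tumor_upper"])
    )
    lower_gv = float(seg["tracer_lower_gv"])
    tracer_mask = threshold_segment(registered, lower_gv, float(registered.values.max()))
    margin_mm = float(seg.get("source_roi_margin_mm", 3.0))
    it = max(int(round(margin_mm / float(min(anatomical.spacing)))), 1)
    roi = ndimage.binary_dilation(tumor_mask.values, iterations=it)
    source_vals = np.where(tracer_mask.values & roi, power.values, 0.0)
    return tumor_mask, power.copy_with(source_vals)


def stage_build(config: CaseConfig, tumor_mask: Mask, source: VoxelImage) -> Phantom:
    ph = config.section("phantom")
    mats = default_materials()
    for name, over in ph.get("materials", {}).items():
        mats[name] = type(mats[name])(**{**mats[name].__dict__, **over})
    return build_phantom(
        tumor_mask,
        source,
        muscle_dims=tuple(ph.get("muscle_dims_mm", (20.0, 20.0, 10.0))),
        embed_fraction=float(ph.get("embed_fraction", 1.0 / 3.0)),
        materials=mats,
    )


def _coil_from_config(config: CaseConfig) -> CoilDrive:
    coil = config.section("coil")
    return CoilDrive(
        field_amplitude=float(coil.get("field_amplitude_kA_per_m", 12.0)) * 1e3,
        frequency=float(coil.get("frequency_khz", 341.25)) * 1e3,
    )


def _schedule_from_config(block: dict) -> HeatingSchedule:
    return HeatingSchedule(
        mode=block.get("mode", "continuous"),
        on_s=float(block.get("on_s", 60.0)),
        off_s=float(block.get("off_s", 30.0)),
        n_cycles=block.get("n_cycles"),
        cutoff_temperature=block.get("cutoff_temperature"),
    )


def stage_simulate(config: CaseConfig, phantom: Phantom, schedule_name: str) -> TemperatureSeries:
    solver = config.section("solver")
    boundary = config.section("boundary")
    trace = None
    if "rectal_trace" in config.raw.get("paths", {}):
        trace = read_timeseries(config.path("rectal_trace"))
    bcs = BoundaryConditions(
        h=float(boundary.get("h", 20.0)),
        t_infinity=float(boundary.get("t_infinity", 37.0)),
        dirichlet_trace=trace if trace is not None else float(boundary.get("t_infinity", 37.0)),
        initial_temperature=float(boundary.get("initial_temperature", 37.0)),
    )
    schedule = _schedule_from_config(config.raw["schedules"][schedule_name])
    return solve_transient(
        phantom,
        _coil_from_config(config),
        schedule,
        bcs,
        dt=float(solver.get("dt_s", 1.0)),
        t_end=float(solver.get("t_end_s", 1800.0)),
        store_every=int(solver.get("store_every", 60)),
    )


def stage_dose(series: TemperatureSeries) -> dict[str, float]:
    """CEM43 (minutes) from the tumor summary trace and the field stack."""
    dose_mean = cem43_from_summary(series.summary, column="tmean_C")
    dose_max = cem43_from_summary(series.summary, column="tmax_C")
    voxelwise = cem43(series)
    peak = float(np.nanmax(voxelwise.cem43)) if voxelwise.is_field else float(voxelwise.cem43)
    return {
        "cem43_tumor_mean_min": dose_mean,
        "cem43_tumor_max_min": dose_max,
        "cem43_voxel_peak_min": peak,
    }


# ---- orchestration -----------------------------------------------------


def _run_stage(name: str, fn, *args, **kw):
    try:
        return fn(*args, **kw)
    except Exception as exc:  # noqa: BLE001 - reporting the stage is the point
        raise StageError(name, exc) from exc


def run_case(config: CaseConfig | str | Path, output_dir=None) -> CaseResult:
    """Execute the full workflow for one case configuration.

    Deterministic given the config and its input files: the pipeline draws
    no randomness.  Results (summary CSVs, CEM43 JSON, field stacks,
    transform, calibration curve, phantom, run log) are written under the
    configured output directory.
    """
    if not isinstance(config, CaseConfig):
        config = CaseConfig.from_yaml(config)
    out = Path(output_dir or config.raw.get("output_dir", config.base_dir / "results"))
    if not out.is_absolute():
        out = config.base_dir / out
    out.mkdir(parents=True, exist_ok=True)

    log: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "stages": [],
    }

    transform, anatomical, registered = _run_stage("register", stage_register, config)
    log["stages"].append({"name": "register", "residual_rms_mm": transform.residual_rms})
    transform.to_json(out / "transform.json")

    curve, power = _run_stage("calibrate", stage_calibrate, config, registered)
    log["stages"].append(
        {"name": "calibrate", "slope": curve.slope, "intercept": curve.intercept,
         "r_squared": curve.r_squared}
    )
    curve.to_json(out / "calibration_curve.json")

    tumor_mask, source = _run_stage(
        "segment", stage_segment, config, anatomical, registered, power
    )
    log["stages"].append(
        {"name": "segment", "tumor_voxels": tumor_mask.voxel_count,
         "tumor_volume_mm3": tumor_mask.volume_mm3}
    )

    phantom = _run_stage("build", stage_build, config, tumor_mask, source)
    log["stages"].append(
        {"name": "build", "total_source_power_W": total_source_power(phantom),
         "clipped_power_W": phantom.clipped_power,
         "realized_embed_fraction": phantom.meta.get("realized_embed_fraction")}
    )
    phantom.to_hdf5(out / "phantom.h5")

    series: dict[str, TemperatureSeries] = {}
    doses: dict[str, dict[str, float]] = {}
    for name in config.raw["schedules"]:
        s = _run_stage("simulate", stage_simulate, config, phantom, name)
        series[name] = s
        s.summary.to_csv(out / f"summary_{name}.csv", index=False)
        with h5py.File(out / f"fields_{name}.h5", "w") as f:
            f.create_dataset("times_s", data=s.times)
            f.create_dataset("fields_C", data=s.fields, compression="gzip")
        doses[name] = _run_stage("dose", stage_dose, s)
        (out / f"cem43_{name}.json").write_text(json.dumps(doses[name], indent=2))
        log["stages"].append(
            {"name": f"simulate:{name}",
             "stopped_by_cutoff": s.stopped_by_cutoff,
             "final_tumor_max_C": float(s.summary["tmax_C"].iloc[-1]),
             **doses[name]}
        )

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return CaseResult(transform, curve, phantom, series, doses, out, log)
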