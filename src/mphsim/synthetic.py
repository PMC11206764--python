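"""Synthetic study fixtures with known ground truth.

Every experimental input of an MPI-guided hyperthermia study is emulated
here so that the whole pipeline is testable without scanner data: a tracer
(MPI-like) image rendered in grayscale values from nanoparticle deposits of
declared iron mass, an anatomical image showing an ellipsoidal tumor and
point-like fiducials, a known ground-truth transform between the two
frames, serial-dilution calibration tables, duty-cycled calorimetry traces,
and a rectal-temperature boundary trace.  All randomness is drawn from a
single seed; fixed seed implies bit-identical outputs.

Default parameters mirror the emulated study: a 100-500 mm^3 subcutaneous
tumor, a ~2 mg Fe/mL intratumor dose of 50 mg Fe/mL stock, SLP 496 W/g at
the 341.25 kHz / 12 kA/m drive, a calibration line GV = 1031 + 1.10e-5 Q,
three fiducial aliquots, and a core temperature held at 37 +/- 0.1 C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    MG_PER_ML_TO_G_PER_M3,
    CalibrationCurve,
    PulseTrace,
)
from .imaging_io import (
    LandmarkSet,
    TimeSeriesTable,
    VoxelImage,
    write_image,
    write_landmarks,
    write_timeseries,
)
from .registration import AffineTransform

__all__ = [
    "BlobSpec",
    "FixtureSpec",
    "generate_image_pair",
    "generate_calibration_table",
    "generate_pulse_trace",
    "generate_rectal_trace",
    "generate_case_dir",
]


@dataclass
class BlobSpec:
    """One nanoparticle deposit: position (anatomical world mm), extent, mass."""

    center_mm: tuple[float, float, float]
    size_mm: float = 1.2  # Gaussian sigma, or radius for kind="ball"
    fe_mass_mg: float = 0.35
    kind: str = "gaussian"  # "gaussian" | "ball"

    def __post_init__(self) -> None:
        if self.fe_mass_mg <= 0:
            raise ValueError("blob iron mass must be positive")
        if self.size_mm <= 0:
            raise ValueError("blob size must be positive")
        if self.kind not in {"gaussian", "ball"}:
            raise ValueError(f"unknown blob kind {self.kind!r}")


def _default_blobs() -> list[BlobSpec]:
    # single deposit at the tumor center; mass = 2 mg/mL x ellipsoid volume
    vol_mm3 = 4.0 / 3.0 * np.pi * 4.0 * 3.5 * 3.0  # ~176 mm^3
    return [BlobSpec((12.0, 12.0, 11.0), 1.2, 2.0 * vol_mm3 / 1000.0)]


@dataclass
class FixtureSpec:
    """Ground-truth description of one synthetic case."""

    seed: int = 0
    # anatomical grid
    anat_shape: tuple[int, int, int] = (48, 48, 36)
    anat_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    # tracer grid (its origin is derived to cover the anatomical volume)
    tracer_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # tumor ellipsoid, anatomical world mm
    tumor_center_mm: tuple[float, float, float] = (12.0, 12.0, 11.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (4.0, 3.5, 3.0)
    # nanoparticle deposits
    blobs: list[BlobSpec] = field(default_factory=_default_blobs)
    psf_sigma_mm: float = 1.0  # tracer point-spread (Gaussian)
    # fiducials, anatomical world mm (three aliquots as in the bench setup)
    fiducials_mm: tuple = ((4.0, 4.0, 4.0), (20.0, 4.0, 6.0), (12.0, 20.0, 5.0))
    fiducial_radius_mm: float = 1.0
    # ground-truth similarity transform tracer->anatomy
    rotation_deg: float = 4.0
    rotation_axis: tuple[float, float, float] = (0.2, 0.3, 0.9)
    translation_mm: tuple[float, float, float] = (3.0, -2.0, 1.5)
    scale: float = 1.0
    # intensities and noise
    noise_gv: float = 5.0
    anat_noise: float = 2.0
    muscle_intensity: float = 50.0
    tumor_intensity: float = 300.0
    fiducial_intensity: float = 1000.0
    fiducial_gv: float = 400.0  # tracer-visible marker amplitude above baseline
    # calibration line and heating
    cal_intercept: float = 1031.0
    cal_slope: float = 1.10e-5  # GV per (W/m^3)
    slp: float = 496.0  # W/g
    cal_concentrations: tuple = (0.0, 0.25, 0.5, 2.5, 5.0, 25.0, 50.0)
    cal_replicates: int = 3
    cal_noise_gv: float = 5.0
    # calorimetry
    calorimeter_heat_capacity: float = 4.18  # J/K (1 mL water sample)
    calorimeter_fe_mass_g: float = 1e-3  # 1 mg Fe
    calorimeter_ambient: float = 25.0
    pulse_on_s: float = 60.0
    pulse_off_s: float = 60.0
    n_pulses: int = 10
    noise_temperature_K: float = 0.05
    # rectal trace
    rectal_baseline: float = 37.0
    rectal_drift: float = 0.1  # max |deviation|, deg C

    def __post_init__(self) -> None:
        if any(b.fe_mass_mg <= 0 for b in self.blobs):
            raise ValueError("declared blob iron mass must be positive")

    @property
    def total_fe_mass_mg(self) -> float:
        return sum(b.fe_mass_mg for b in self.blobs)

    def ground_truth_transform(self) -> AffineTransform:
        """Similarity transform mapping tracer world -> anatomical world."""
        axis = np.asarray(self.rotation_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(self.rotation_deg)
        kx, ky, kz = axis
        kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
        rot = np.eye(3) + np.sin(th) * kmat + (1 - np.cos(th)) * (kmat @ kmat)
        return AffineTransform.from_linear(
            self.scale * rot, np.asarray(self.translation_mm, dtype=float)
        )

    def calibration_curve(self) -> CalibrationCurve:
        return CalibrationCurve(
            slope=self.cal_slope,
            intercept=self.cal_intercept,
            r_squared=1.0,
            slp_used=self.slp,
        )


def _concentration_field(spec: FixtureSpec, grid: VoxelImage, to_anat) -> np.ndarray:
    """Iron concentration (mg/mL == g/L) sampled at grid voxel centers.

    ``to_anat`` maps the grid's world coordinates into the anatomical frame
    where blob centers are declared.  Gaussian deposits carry the tracer
    point-spread folded in (sigma_eff^2 = sigma^2 + psf^2), which keeps the
    integrated mass exact.
    """
    world = grid.world_grid().reshape(-1, 3)
    anat = np.atleast_2d(to_anat(world))
    conc = np.zeros(len(anat))  # mg per mm^3
    for blob in spec.blobs:
        d2 = np.sum((anat - np.asarray(blob.center_mm)) ** 2, axis=1)
        if blob.kind == "gaussian":
            s2 = blob.size_mm**2 + spec.psf_sigma_mm**2
            kernel = np.exp(-d2 / (2 * s2)) / (2 * np.pi * s2) ** 1.5  # 1/mm^3
        else:  # uniform ball
            vol = 4.0 / 3.0 * np.pi * blob.size_mm**3
            kernel = (d2 <= blob.size_mm**2) / vol
        conc += blob.fe_mass_mg * kernel
    return (conc * 1000.0).reshape(grid.shape)  # mg/mm^3 -> mg/mL


def generate_image_pair(spec: FixtureSpec):
    """Render the tracer/anatomical image pair with matched fiducials.

    Returns ``(tracer, anatomical, fixed_landmarks, moving_landmarks,
    truth)`` where ``truth`` maps tracer world coordinates onto anatomical
    ones and the landmark sets are exact (noise on fiducial localization is
    the registration tests' business, not the generator's).
    """
    rng = np.random.default_rng(spec.seed)
    truth = spec.ground_truth_transform()
    inv = truth.inverse()

    # anatomical image: tumor ellipsoid + fiducial spheres on a tissue bed
    anat_grid = VoxelImage(
        np.zeros(spec.anat_shape), np.asarray(spec.anat_spacing_mm)
    )
    for blob in spec.blobs:
        idx = anat_grid.world_to_index(np.asarray(blob.center_mm, dtype=float))
        if np.any(idx < 0) or np.any(idx > np.array(spec.anat_shape) - 1):
            raise ValueError(f"blob center {blob.center_mm} lies outside the grid")
    world = anat_grid.world_grid()
    rel = (world - np.asarray(spec.tumor_center_mm)) / np.asarray(
        spec.tumor_semiaxes_mm
    )
    anat_vals = np.full(spec.anat_shape, spec.muscle_intensity)
    anat_vals[np.sum(rel**2, axis=-1) <= 1.0] = spec.tumor_intensity
    for f in spec.fiducials_mm:
        d2 = np.sum((world - np.asarray(f)) ** 2, axis=-1)
        anat_vals[d2 <= spec.fiducial_radius_mm**2] = spec.fiducial_intensity
    if spec.anat_noise > 0:
        anat_vals = anat_vals + rng.normal(0, spec.anat_noise, spec.anat_shape)
    anatomical = anat_grid.copy_with(anat_vals)

    # tracer grid: cover the anatomical volume mapped into the tracer frame
    corners = np.array(
        [
            anat_grid.index_to_world(np.array(c) * (np.array(spec.anat_shape) - 1))
            for c in np.ndindex(2, 2, 2)
        ]
    )
    tr_corners = np.atleast_2d(inv.apply(corners))
    spacing = np.asarray(spec.tracer_spacing_mm)
    lo = tr_corners.min(axis=0) - 2.0
    hi = tr_corners.max(axis=0) + 2.0
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    tracer_grid = VoxelImage(np.zeros(shape), spacing, origin=lo)

    conc = _concentration_field(spec, tracer_grid, truth.apply)
    q = spec.slp * conc * MG_PER_ML_TO_G_PER_M3  # W/m^3
    gv = spec.cal_intercept + spec.cal_slope * q
    tr_world = tracer_grid.world_grid()
    for f in spec.fiducials_mm:
        fm = np.asarray(inv.apply(np.asarray(f, dtype=float)))
        d2 = np.sum((tr_world - fm) ** 2, axis=-1)
        gv = gv + spec.fiducial_gv * np.exp(-d2 / (2 * spec.fiducial_radius_mm**2))
    if spec.noise_gv > 0:
        gv = gv + rng.normal(0, spec.noise_gv, shape)
    tracer = tracer_grid.copy_with(gv)

    fixed = LandmarkSet(np.array(spec.fiducials_mm, dtype=float))
    moving = LandmarkSet(np.atleast_2d(inv.apply(fixed.points)))
    return tracer, anatomical, fixed, moving, truth


def generate_calibration_table(spec: FixtureSpec) -> pd.DataFrame:
    """Serial-dilution table (concentration_mg_per_ml, replicate, max_gv)."""
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for conc in spec.cal_concentrations:
        q = spec.slp * conc * MG_PER_ML_TO_G_PER_M3
        for rep in range(spec.cal_replicates):
            gv = spec.cal_intercept + spec.cal_slope * q
            if spec.cal_noise_gv > 0:
                gv += rng.normal(0, spec.cal_noise_gv)
            rows.append(
                {
                    "concentration_mg_per_ml": conc,
                    "replicate": rep,
                    "max_gv": gv,
                }
            )
    return pd.DataFrame(rows)


def generate_pulse_trace(
    spec: FixtureSpec, slp: float | None = None, loss_coefficient: float = 5e-3
) -> PulseTrace:
    """Forward-integrate the lumped calorimetry model over the pulse train.

    The sample (heat capacity C, iron mass m_Fe) follows
    C dT/dt = P chi_on - L (T - T_amb) with P = slp * m_Fe; seeded Gaussian
    measurement noise is added to the sampled temperatures.
    """
    if slp is None:
        slp = spec.slp
    if slp < 0:
        raise ValueError("slp must be nonnegative")
    rng = np.random.default_rng(spec.seed + 2)
    period = spec.pulse_on_s + spec.pulse_off_s
    schedule = [
        (i * period, i * period + spec.pulse_on_s) for i in range(spec.n_pulses)
    ]
    t_end = spec.n_pulses * period
    times = np.arange(0.0, t_end + 0.5, 1.0)  # 1 s thermometry cadence
    power = slp * spec.calorimeter_fe_mass_g

    from .calibration import _simulate_lumped

    temps = _simulate_lumped(
        times,
        schedule,
        power,
        loss_coefficient,
        spec.calorimeter_heat_capacity,
        spec.calorimeter_ambient,
        spec.calorimeter_ambient,
    )
    if spec.noise_temperature_K > 0:
        temps = temps + rng.normal(0, spec.noise_temperature_K, temps.shape)
    return PulseTrace(
        times=times,
        temperatures=temps,
        schedule=schedule,
        fe_mass=spec.calorimeter_fe_mass_g,
        heat_capacity=spec.calorimeter_heat_capacity,
        ambient=spec.calorimeter_ambient,
    )


def generate_rectal_trace(spec: FixtureSpec, t_end: float) -> TimeSeriesTable:
    """Smooth core-temperature trace near 37 C covering [0, t_end].

    A seeded random walk is smoothed and rescaled so the drift never
    exceeds ``rectal_drift`` (the +/- 0.1 C regulation band of the water
    circulation), then offset by the baseline.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(spec.seed + 3)
    times = np.arange(0.0, float(t_end) + 1.0, 1.0)
    if spec.rectal_drift > 0:
        walk = np.cumsum(rng.normal(0, 1.0, len(times)))
        kernel = np.ones(61) / 61.0
        smooth = np.convolve(walk, kernel, mode="same")
        smooth -= smooth.mean()
        peak = np.max(np.abs(smooth))
        drift = spec.rectal_drift * smooth / peak if peak > 0 else smooth
    else:
        drift = np.zeros(len(times))
    return TimeSeriesTable(times, spec.rectal_baseline + drift)


def default_case_config(spec: FixtureSpec, t_end: float = 1800.0) -> dict:
    """A runnable case configuration matching the generated fixtures."""
    return {
        "paths": {
            "tracer": "tracer.nii.gz",
            "anatomical": "anatomical.nii.gz",
            "landmarks_fixed": "landmarks_anatomical.csv",
            "landmarks_moving": "landmarks_tracer.csv",
            "calibration": "calibration.csv",
            "rectal_trace": "rectal.csv",
        },
        "registration": {"model": "similarity"},
        "calibration": {"slp": spec.slp},
        "segmentation": {
            "tumor_lower": (spec.muscle_intensity + spec.tumor_intensity) / 2,
            "tumor_upper": (spec.tumor_intensity + spec.fiducial_intensity) / 2,
            # manual tracer bound: just above the zero-power baseline + noise
            "tracer_lower_gv": spec.cal_intercept + max(2 * spec.noise_gv, 1.0),
            "source_roi_margin_mm": 3.0,
        },
        "phantom": {"muscle_dims_mm": [20.0, 20.0, 10.0], "embed_fraction": 1 / 3},
        "coil": {"field_amplitude_kA_per_m": 12.0, "frequency_khz": 341.25},
        "boundary": {"h": 20.0, "t_infinity": 37.0, "initial_temperature": 37.0},
        "solver": {"dt_s": 1.0, "t_end_s": t_end, "store_every": 60},
        "schedules": {
            "continuous": {"mode": "continuous", "cutoff_temperature": 51.0},
            "pulsed": {"mode": "pulsed", "on_s": 60.0, "off_s": 30.0, "n_cycles": 20},
        },
        "output_dir": "results",
    }


def generate_case_dir(spec: FixtureSpec, out_dir, t_end: float = 1800.0) -> Path:
    """Write a complete case directory: images, landmark CSVs, calibration
    CSV, rectal trace, case config, and the ground-truth JSON."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracer, anatomical, fixed, moving, truth = generate_image_pair(spec)
    write_image(tracer, out / "tracer.nii.gz")
    write_image(anatomical, out / "anatomical.nii.gz")
    write_landmarks(fixed, out / "landmarks_anatomical.csv")
    write_landmarks(moving, out / "landmarks_tracer.csv")
    generate_calibration_table(spec).to_csv(out / "calibration.csv", index=False)
    write_timeseries(generate_rectal_trace(spec, t_end), out / "rectal.csv")
    truth.to_json(out / "ground_truth_transform.json")
    (out / "case.yaml").write_text(
        yaml.safe_dump(default_case_config(spec, t_end=t_end), sort_keys=False)
    )
    meta = asdict(spec)
    meta["blobs"] = [asdict(b) for b in spec.blobs]
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2, default=list))
    return out
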