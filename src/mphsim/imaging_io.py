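"""Voxel-image and tabular I/O plus grid geometry.

World coordinates are in millimetres on LPS axes (the SimpleITK/ITK
convention); voxel indices are 0-based and refer to voxel *centers*.  The
mapping between the two is

    world = origin + orientation @ (spacing * index)

with ``orientation`` a 3x3 direction-cosine matrix.  All physical solver
quantities are SI internally; millimetres appear only at this I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "VoxelImage",
    "LandmarkSet",
    "TimeSeriesTable",
    "read_image",
    "write_image",
    "read_landmarks",
    "write_landmarks",
    "read_timeseries",
    "write_timeseries",
]

_KNOWN_FORMATS = {"nifti": (".nii", ".nii.gz"), "nrrd": (".nrrd",)}


@dataclass
class VoxelImage:
    """A 3D scalar lattice with grid geometry.

    ``values[i, j, k]`` is the sample at voxel index ``(i, j, k)``; the
    value may be a tracer grayscale value (GV), an anatomical intensity, or
    a physical quantity such as volumetric power (W/m^3).
    """

    values: np.ndarray
    spacing: np.ndarray  # mm, per axis
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # mm
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"VoxelImage requires 3D data, got ndim={self.values.ndim}"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive components (mm)")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")
        if self.orientation.shape != (3, 3) or not np.allclose(
            self.orientation.T @ self.orientation, np.eye(3), atol=1e-9
        ):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VoxelImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.orientation, other.orientation)
        )

    def copy_with(self, values: np.ndarray) -> "VoxelImage":
        """New image with the same geometry and different values."""
        return VoxelImage(
            np.asarray(values, dtype=float),
            self.spacing.copy(),
            self.origin.copy(),
            self.orientation.copy(),
        )

    # ---- grid geometry -------------------------------------------------

    def index_to_world(self, index) -> np.ndarray:
        """Continuous voxel index -> world point (mm)."""
        index = np.atleast_2d(np.asarray(index, dtype=float))
        pts = (self.orientation @ (index * self.spacing).T).T + self.origin
        return pts if pts.shape[0] > 1 else pts[0]

    def world_to_index(self, point) -> np.ndarray:
        """World point (mm) -> continuous voxel index (may lie off-grid)."""
        point = np.atleast_2d(np.asarray(point, dtype=float))
        if not np.all(np.isfinite(point)):
            raise ValueError("point must be finite")
        idx = (self.orientation.T @ (point - self.origin).T).T / self.spacing
        return idx if idx.shape[0] > 1 else idx[0]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*grid, 3), mm."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
            axis=-1,
        ).astype(float)
        flat = idx.reshape(-1, 3)
        world = (self.orientation @ (flat * self.spacing).T).T + self.origin
        return world.reshape(*self.shape, 3)


def world_to_index(image: VoxelImage, point) -> np.ndarray:
    return image.world_to_index(point)


def index_to_world(image: VoxelImage, index) -> np.ndarray:
    return image.index_to_world(index)


@dataclass
class LandmarkSet:
    """Ordered fiducial coordinates (mm); order defines correspondence."""

    points: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.points) < 3:
            raise ValueError("at least 3 fiducials are required")
        if self.labels is None:
            self.labels = [f"F{i}" for i in range(len(self.points))]
        d = np.linalg.norm(
            self.points[:, None, :] - self.points[None, :, :], axis=-1
        )
        if np.any(d[np.triu_indices(len(self.points), k=1)] < 1e-12):
            raise ValueError("duplicate fiducial points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TimeSeriesTable:
    """A scalar time series; times in seconds, strictly increasing."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1D arrays")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("times and values must be finite")

    def at(self, t) -> np.ndarray:
        """Linear interpolation, clamped at the endpoints."""
        return np.interp(t, self.times, self.values)

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


# ---- file I/O ----------------------------------------------------------


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    for fmt, exts in _KNOWN_FORMATS.items():
        if any(name.endswith(e) for e in exts):
            return fmt
    raise ValueError(f"cannot infer image format from {path.name!r}")


def read_image(path, format: str | None = None) -> VoxelImage:
    """Read a NIfTI-1 or NRRD volume into a :class:`VoxelImage`.

    SimpleITK returns arrays indexed (k, j, i); we transpose so that
    ``values[i, j, k]`` matches ITK index order and the stored geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D image, got {img.GetDimension()}D")
    values = sitk.GetArrayFromImage(img).T  # (i, j, k)
    return VoxelImage(
        values=np.asarray(values, dtype=float),
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        orientation=np.array(img.GetDirection()).reshape(3, 3),
    )


def write_image(image: VoxelImage, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}")
    img = sitk.GetImageFromArray(image.values.T)
    img.SetSpacing(tuple(image.spacing))
    img.SetOrigin(tuple(image.origin))
    img.SetDirection(tuple(image.orientation.ravel()))
    sitk.WriteImage(img, str(path))


def read_landmarks(path) -> LandmarkSet:
    """CSV with columns label,x_mm,y_mm,z_mm (ordered correspondence)."""
    df = pd.read_csv(path)
    required = {"label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    return LandmarkSet(
        points=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        labels=list(df["label"].astype(str)),
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    pd.DataFrame(
        {
            "label": list(landmarks.labels),
            "x_mm": landmarks.points[:, 0],
            "y_mm": landmarks.points[:, 1],
            "z_mm": landmarks.points[:, 2],
        }
    ).to_csv(path, index=False)


def read_timeseries(path) -> TimeSeriesTable:
    """CSV with columns t_s,value."""
    df = pd.read_csv(path)
    if not {"t_s", "value"}.issubset(df.columns):
        raise ValueError("time-series CSV must have columns t_s,value")
    return TimeSeriesTable(df["t_s"].to_numpy(float), df["value"].to_numpy(float))


def write_timeseries(series: TimeSeriesTable, path) -> None:
    pd.DataFrame({"t_s": series.times, "value": series.values}).to_csv(
        path, index=False
    )
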