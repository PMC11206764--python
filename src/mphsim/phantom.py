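"""Segmentation and assembly of the computational tumor-in-muscle phantom.

The phantom is a single structured voxel grid carrying three labels (air,
muscle, tumor), per-label material properties, and a nonnegative volumetric
nanoparticle heat-source lattice Q_MNP (W/m^3).  The tumor sits partially
embedded in a muscle cuboid — by default one third of its volume below the
muscle top plane, mimicking a subcutaneous mass — with air above.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import h5py
import numpy as np
import yaml

from .imaging_io import VoxelImage

__all__ = [
    "AIR",
    "MUSCLE",
    "TUMOR",
    "Mask",
    "MaterialProperties",
    "Phantom",
    "default_materials",
    "threshold_segment",
    "signal_capture_fraction",
    "build_phantom",
    "total_source_power",
]

AIR, MUSCLE, TUMOR = 0, 1, 2
_LABEL_NAMES = {AIR: "air", MUSCLE: "muscle", TUMOR: "tumor"}


@dataclass
class Mask:
    """Boolean lattice tied to the grid geometry of a parent image."""

    values: np.ndarray
    grid: VoxelImage  # geometry carrier; its values are ignored

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape must match its parent grid")

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3


@dataclass
class MaterialProperties:
    """Bulk thermal and electromagnetic tissue properties (SI)."""

    density: float  # kg/m^3
    specific_heat: float  # J/(kg K)
    conductivity: float  # W/(m K)
    electrical_conductivity: float  # S/m
    relative_permeability: float = 1.0
    relative_permittivity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "conductivity", "electrical_conductivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.relative_permeability < 1 or self.relative_permittivity < 1:
            raise ValueError("relative permeability/permittivity must be >= 1")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c_p, J/(m^3 K)."""
        return self.density * self.specific_heat


def default_materials() -> dict[str, MaterialProperties]:
    """Muscle and tumor properties shipped with the package."""
    ref = importlib.resources.files("mphsim").joinpath("data/default_materials.yaml")
    raw = yaml.safe_load(ref.read_text())
    return {name: MaterialProperties(**props) for name, props in raw.items()}


@dataclass
class Phantom:
    """Labeled voxel phantom with materials and the Q_MNP source field."""

    labels: np.ndarray  # int lattice of AIR/MUSCLE/TUMOR
    grid: VoxelImage  # geometry carrier
    materials: Mapping[str, MaterialProperties]
    source: np.ndarray  # W/m^3, same shape
    embed_fraction: float = 1.0 / 3.0
    muscle_top_k: int | None = None  # first air k-layer above the muscle slab
    clipped_power: float = 0.0  # W removed because it fell into air
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.source = np.asarray(self.source, dtype=float)
        if self.labels.shape != self.grid.shape or self.source.shape != self.grid.shape:
            raise ValueError("labels and source must match the grid shape")
        if np.any(self.source < 0):
            raise ValueError("source must be nonnegative")
        if np.any(self.source[self.labels == AIR] != 0):
            raise ValueError("source must vanish outside tumor and muscle")
        if not 0 < self.embed_fraction <= 1:
            raise ValueError("embed_fraction must lie in (0, 1]")
        for lbl in ("muscle", "tumor"):
            if lbl not in self.materials:
                raise ValueError(f"materials must define {lbl!r}")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == TUMOR

    @property
    def solid_mask(self) -> np.ndarray:
        return self.labels != AIR

    def property_field(self, name: str) -> np.ndarray:
        """Per-voxel lattice of a material property (0 in air)."""
        out = np.zeros(self.grid.shape)
        for code, lname in _LABEL_NAMES.items():
            if lname in self.materials:
                out[self.labels == code] = getattr(self.materials[lname], name)
        return out

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels, compression="gzip")
            f.create_dataset("source", data=self.source, compression="gzip")
            f.attrs["spacing_mm"] = self.grid.spacing
            f.attrs["origin_mm"] = self.grid.origin
            f.attrs["embed_fraction"] = self.embed_fraction
            f.attrs["clipped_power_W"] = self.clipped_power
            mats = f.create_group("materials")
            for name, m in self.materials.items():
                g = mats.create_group(name)
                for k, v in m.__dict__.items():
                    g.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "Phantom":
        with h5py.File(path, "r") as f:
            labels = f["labels"][()]
            source = f["source"][()]
            grid = VoxelImage(
                np.zeros(labels.shape), f.attrs["spacing_mm"], f.attrs["origin_mm"]
            )
            materials = {
                name: MaterialProperties(**dict(g.attrs))
                for name, g in f["materials"].items()
            }
            return cls(
                labels,
                grid,
                materials,
                source,
                embed_fraction=float(f.attrs["embed_fraction"]),
                clipped_power=float(f.attrs["clipped_power_W"]),
            )


def threshold_segment(image: VoxelImage, lower: float, upper: float) -> Mask:
    """Inclusive band threshold: mask where lower <= value <= upper.

    Mirrors manual tracer segmentation where the upper bound is the image
    maximum and the lower bound is chosen per case.
    """
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    values = (image.values >= lower) & (image.values <= upper)
    if not values.any():
        warnings.warn("threshold produced an empty mask", stacklevel=2)
    return Mask(values, image)


def signal_capture_fraction(image: VoxelImage, tumor_mask: Mask, lower: float) -> float:
    """Fraction of in-tumor signal captured by a candidate lower bound.

    Helps pick the manual threshold so that the majority of tracer signal
    inside the tumor is encompassed by the mask.
    """
    inside = image.values[tumor_mask.values]
    total = inside.sum()
    if total <= 0:
        return 0.0
    return float(inside[inside >= lower].sum() / total)


def build_phantom(
    tumor_mask: Mask,
    source_image: VoxelImage,
    muscle_dims: tuple[float, float, float],
    embed_fraction: float = 1.0 / 3.0,
    materials: Mapping[str, MaterialProperties] | None = None,
    air_margin_voxels: int = 2,
    extra_depth_voxels: int = 0,
) -> Phantom:
    """Assemble the tumor-in-muscle phantom on a fresh structured grid.

    The tumor (and its co-registered Q_MNP source) is translated so that it
    is centered laterally on the muscle cuboid's top face, with the chosen
    fraction of its voxels below the top plane.  The embedding depth is
    found by scanning integer voxel offsets, so the realized fraction is
    within one voxel layer of the request.  Source power falling into air
    after placement is clipped and reported.

    Parameters
    ----------
    muscle_dims : (x, y, z) extent of the muscle cuboid in mm.
    """
    if tumor_mask.voxel_count == 0:
        raise ValueError("tumor mask is empty")
    if not tumor_mask.grid.same_grid(source_image):
        raise ValueError("tumor mask and source image must share a grid")
    if materials is None:
        materials = default_materials()
    spacing = tumor_mask.grid.spacing
    muscle_shape = np.maximum(np.round(np.asarray(muscle_dims) / spacing), 1).astype(int)

    # tumor bounding box on its native grid
    idx = np.argwhere(tumor_mask.values)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    tumor = tumor_mask.values[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    tshape = np.array(tumor.shape)
    if np.any(tshape[:2] + 2 * air_margin_voxels > muscle_shape[:2]):
        raise ValueError("tumor is too large for the muscle cuboid footprint")

    # choose the integer number of embedded tumor layers matching the fraction
    ntot = tumor.sum()
    layer_counts = tumor.sum(axis=(0, 1))  # per native k-layer
    cum = np.cumsum(layer_counts)
    depth = int(np.argmin(np.abs(cum / ntot - embed_fraction))) + 1
    frac_below = float(cum[depth - 1] / ntot)
    if embed_fraction >= 1.0:
        depth = int(tshape[2])
        frac_below = 1.0
    depth += int(extra_depth_voxels)  # bury deeper (verification/deep-seated)
    if depth + air_margin_voxels > muscle_shape[2]:
        raise ValueError("tumor embedding deeper than the muscle cuboid allows")

    protrude = max(int(tshape[2]) - depth, 0)
    nz = int(muscle_shape[2]) + protrude + air_margin_voxels
    shape = (int(muscle_shape[0]), int(muscle_shape[1]), nz)
    labels = np.full(shape, AIR, dtype=np.int8)
    src = np.zeros(shape)

    top_k = int(muscle_shape[2])  # first k-layer above the muscle slab
    labels[:, :, :top_k] = MUSCLE

    # lateral centering; embedded layers end at the top plane
    off_x = (shape[0] - tshape[0]) // 2
    off_y = (shape[1] - tshape[1]) // 2
    off_z = top_k - depth
    sl = (
        slice(off_x, off_x + tshape[0]),
        slice(off_y, off_y + tshape[1]),
        slice(off_z, off_z + tshape[2]),
    )
    labels[sl][tumor] = TUMOR

    # translate the whole source lattice by the same offset as the tumor;
    # positive power landing in air (or off-grid) is clipped and reported
    shift = np.array([off_x, off_y, off_z]) - lo
    pos = np.argwhere(source_image.values > 0)
    vals = source_image.values[tuple(pos.T)] if len(pos) else np.empty(0)
    dest = pos + shift
    inb = np.all((dest >= 0) & (dest < np.array(shape)), axis=1)
    kept = np.zeros(len(pos), dtype=bool)
    if len(pos):
        d = dest[inb]
        solid = labels[tuple(d.T)] != AIR
        src[tuple(d[solid].T)] += vals[inb][solid]
        kept[np.flatnonzero(inb)[solid]] = True
    voxel_m3 = float(np.prod(spacing)) * 1e-9
    clipped = float(vals[~kept].sum() * voxel_m3)  # W

    grid = VoxelImage(np.zeros(shape), spacing, origin=np.zeros(3))
    return Phantom(
        labels,
        grid,
        materials,
        np.maximum(src, 0.0),
        embed_fraction=embed_fraction,
        muscle_top_k=top_k,
        clipped_power=clipped,
        meta={"realized_embed_fraction": frac_below},
    )


def total_source_power(phantom: Phantom) -> float:
    """Total nanoparticle power, W: sum of Q_MNP times voxel volume."""
    voxel_m3 = phantom.grid.voxel_volume_mm3 * 1e-9
    return float(phantom.source.sum() * voxel_m3)
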