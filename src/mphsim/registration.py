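"""Fiducial landmark co-registration and voxel-image resampling.

The transform is a 4x4 homogeneous matrix A mapping world points (mm) in the
moving modality (tracer/MPI) onto the fixed modality (anatomy).  The closed
form least-squares estimators are:

* ``rigid`` / ``similarity``: Kabsch/Umeyama SVD solution (rotation +
  translation, optionally an isotropic scale).  Three non-collinear
  fiducials suffice.
* ``affine``: unconstrained 12-dof linear least squares; needs at least four
  non-coplanar fiducials.

Three fiducial aliquots, the typical experimental setup, cannot determine a
full affine, hence ``similarity`` is the default model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import LandmarkSet, VoxelImage

__all__ = ["AffineTransform", "estimate_transform", "resample"]


@dataclass
class AffineTransform:
    """4x4 homogeneous world->world transform (mm).

    The upper-left 3x3 block rotates/scales/shears, the upper-right column
    translates; the last row is exactly (0, 0, 0, 1).
    """

    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.array_equal(self.matrix[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row must be exactly (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) <= 1e-12:
            raise ValueError("transform is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_linear(cls, linear: np.ndarray, translation: np.ndarray, **kw) -> "AffineTransform":
        m = np.eye(4)
        m[:3, :3] = linear
        m[:3, 3] = translation
        return cls(m, **kw)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.translation
        return out if out.shape[0] > 1 else out[0]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self o other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"matrix": self.matrix.tolist(), "residual_rms_mm": self.residual_rms},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["matrix"]), d.get("residual_rms_mm", 0.0))


def _umeyama(moving: np.ndarray, fixed: np.ndarray, with_scale: bool):
    """Closed-form least-squares rotation/translation(/scale) fit."""
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    xm = moving - mu_m
    xf = fixed - mu_f
    cov = xf.T @ xm / len(moving)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    sgn = np.diag([1.0, 1.0, d])
    rot = u @ sgn @ vt
    if with_scale:
        var_m = (xm**2).sum() / len(moving)
        scale = float(np.trace(np.diag(s) @ sgn) / var_m)
    else:
        scale = 1.0
    trans = mu_f - scale * rot @ mu_m
    return scale * rot, trans


def estimate_transform(
    fixed: LandmarkSet, moving: LandmarkSet, model: str = "similarity"
) -> AffineTransform:
    """Least-squares transform taking ``moving`` fiducials onto ``fixed``.

    Correspondence is by row order.  The residual RMS (mm) of the fit is
    stored on the returned transform.

    Parameters
    ----------
    model : {"rigid", "similarity", "affine"}
        ``similarity`` (default) adds an isotropic scale to a rigid motion;
        ``affine`` is an unconstrained 12-dof fit requiring >=4 non-coplanar
        points.
    """
    if model not in {"rigid", "similarity", "affine"}:
        raise ValueError(f"unknown model {model!r}")
    if len(fixed) != len(moving):
        raise ValueError("fixed and moving landmark counts differ")
    f = fixed.points
    m = moving.points
    if model == "affine":
        if len(f) < 4:
            raise ValueError("affine model needs at least 4 landmarks")
        # non-coplanarity: centered moving points must span 3 dimensions
        sv = np.linalg.svd(m - m.mean(axis=0), compute_uv=False)
        if sv[-1] < 1e-9 * max(sv[0], 1.0):
            raise ValueError("landmarks are coplanar; affine fit is degenerate")
        hom = np.hstack([m, np.ones((len(m), 1))])
        coef, *_ = np.linalg.lstsq(hom, f, rcond=None)
        linear, trans = coef[:3].T, coef[3]
    else:
        linear, trans = _umeyama(m, f, with_scale=(model == "similarity"))
    pred = m @ linear.T + trans
    rms = float(np.sqrt(np.mean(np.sum((pred - f) ** 2, axis=1))))
    return AffineTransform.from_linear(linear, trans, residual_rms=rms)


def resample(
    image: VoxelImage,
    transform: AffineTransform,
    target_grid: VoxelImage,
    interpolation: str = "trilinear",
    fill_value: float = 0.0,
) -> VoxelImage:
    """Pull ``image`` through ``transform`` onto the geometry of ``target_grid``.

    Each target voxel center is mapped through the *inverse* transform into
    the source image and sampled there; points outside the source lattice
    take ``fill_value`` (default 0, i.e. no tracer).
    """
    orders = {"nearest": 0, "trilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    inv = transform.inverse()
    tgt_world = target_grid.world_grid().reshape(-1, 3)
    src_world = np.atleast_2d(inv.apply(tgt_world))
    src_idx = np.atleast_2d(image.world_to_index(src_world))
    values = ndimage.map_coordinates(
        image.values,
        src_idx.T,
        order=orders[interpolation],
        mode="constant",
        cval=fill_value,
    )
    return target_grid.copy_with(values.reshape(target_grid.shape))
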