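"""Transient heat conduction with nanoparticle and eddy-current heating.

The temperature field obeys Fourier conduction with two volumetric sources,

    rho c_p dT/dt = div(k grad T) + s(t) * (Q_MNP + Q_eddy),

where ``s(t)`` is the duty-cycle indicator of the applied field.  The
equation is discretized by a finite-volume scheme on the phantom's voxel
grid (harmonic-mean face conductivities across material interfaces) and
integrated with backward Euler, which is unconditionally stable on the
stiff fine-voxel lattice.  Boundary conditions follow the cadaver heating
setup: a convective (Robin) condition q = h (T - T_inf) on every exposed
solid/air face, and a time-interpolated uniform Dirichlet temperature —
the rectal trace — on the five non-top faces of the muscle cuboid.

Eddy-current heating uses the magnetoquasistatic closed form.  At the
tissue conductivities and the ~341 kHz drive used for hyperthermia the
skin depth (~1.8 m) vastly exceeds the phantom, so the applied axial field
is undisturbed and the induced Joule heating at radial distance r from the
coil axis is

    Q_eddy(r) = sigma * (omega mu0 mu_r H0)^2 * r^2 / 8      [W/m^3]

with H0 the *peak* field amplitude (the 1/2 time-average factor of the
phasor convention is folded into the 1/8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla

from .imaging_io import TimeSeriesTable, VoxelImage
from .phantom import AIR, Mask, MaterialProperties, Phantom

__all__ = [
    "MU0",
    "CoilDrive",
    "HeatingSchedule",
    "BoundaryConditions",
    "TemperatureSeries",
    "schedule_factor",
    "eddy_power_density",
    "solve_transient",
    "solve_steady_dirichlet",
    "summarize",
]

MU0 = 4e-7 * math.pi  # vacuum permeability, H/m

_DIRECT_SOLVE_MAX = 60_000  # unknowns; beyond this use preconditioned CG


@dataclass
class CoilDrive:
    """Axial AMF drive: peak amplitude H0 (A/m) and frequency f (Hz)."""

    field_amplitude: float  # A/m, peak
    frequency: float  # Hz
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_point: np.ndarray | None = None  # world mm; default: source centroid
    amplitude_convention: str = "peak"

    def __post_init__(self) -> None:
        if self.amplitude_convention != "peak":
            raise ValueError(
                "field_amplitude must be supplied as a peak value; "
                "convert RMS inputs before constructing CoilDrive"
            )
        if self.field_amplitude < 0:
            raise ValueError("field_amplitude must be nonnegative")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be a nonzero vector")
        self.axis = self.axis / n
        if self.axis_point is not None:
            self.axis_point = np.asarray(self.axis_point, dtype=float)

    @property
    def omega(self) -> float:
        return 2 * math.pi * self.frequency

    @classmethod
    def from_flux_density(cls, b_peak_mT: float, frequency: float, **kw) -> "CoilDrive":
        """Build from a peak flux density in mT (vacuum: H = B/mu0)."""
        return cls(b_peak_mT * 1e-3 / MU0, frequency, **kw)


@dataclass
class HeatingSchedule:
    """Continuous or duty-cycled field schedule with an optional cutoff."""

    mode: str = "continuous"  # "continuous" | "pulsed"
    on_s: float = 60.0
    off_s: float = 30.0
    n_cycles: int | None = None
    cutoff_temperature: float | None = None  # deg C, on the tumor maximum

    def __post_init__(self) -> None:
        if self.mode not in {"continuous", "pulsed"}:
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.on_s <= 0 or self.off_s < 0:
            raise ValueError("on_s must be > 0 and off_s >= 0")

    @property
    def duty(self) -> float:
        if self.mode == "continuous":
            return 1.0
        return self.on_s / (self.on_s + self.off_s)

    @property
    def total_on_time(self) -> float | None:
        if self.mode == "pulsed" and self.n_cycles is not None:
            return self.n_cycles * self.on_s
        return None


def schedule_factor(schedule: HeatingSchedule, t: float) -> float:
    """Field indicator at time t: 1 when the AMF is ON, else 0."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if schedule.mode == "continuous":
        return 1.0
    period = schedule.on_s + schedule.off_s
    if schedule.n_cycles is not None and t >= schedule.n_cycles * period:
        return 0.0
    return 1.0 if (t % period) < schedule.on_s else 0.0


def eddy_power_density(
    material: MaterialProperties, drive: CoilDrive, r
) -> np.ndarray | float:
    """Time-averaged eddy-current Joule heating at radius r (m), W/m^3."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be nonnegative")
    amp = drive.omega * MU0 * material.relative_permeability * drive.field_amplitude
    q = material.electrical_conductivity * amp**2 * r**2 / 8.0
    return q if q.ndim else float(q)


@dataclass
class BoundaryConditions:
    """Robin top surface + Dirichlet rectal-temperature sides, initial field.

    ``dirichlet_trace`` may be a :class:`TimeSeriesTable` (interpolated in
    time), a constant temperature, or ``None`` — in which case the five
    non-top cuboid faces are treated as insulated (zero flux), which the
    closed-form verification problems rely on.
    """

    h: float = 20.0  # W/(m^2 K) on exposed solid/air faces
    t_infinity: float = 37.0  # deg C
    dirichlet_trace: TimeSeriesTable | float | None = None
    initial_temperature: float | np.ndarray = 37.0  # deg C

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be nonnegative")

    @property
    def has_dirichlet(self) -> bool:
        return self.dirichlet_trace is not None

    def dirichlet_at(self, t: float) -> float:
        if self.dirichlet_trace is None:
            raise ValueError("no Dirichlet boundary configured")
        if isinstance(self.dirichlet_trace, TimeSeriesTable):
            return float(self.dirichlet_trace.at(t))
        return float(self.dirichlet_trace)


@dataclass
class TemperatureSeries:
    """Stored temperature lattices plus the per-step tumor summary.

    ``fields[m]`` is the lattice at ``times[m]``; air voxels hold NaN.
    ``summary`` covers *every* solver step (t_s, tmax_C, tmin_C, tmean_C
    over the tumor), which is what dosimetry consumes.
    """

    times: np.ndarray  # s, stored-field times
    fields: np.ndarray  # (n_stored, nx, ny, nz), deg C; NaN in air
    summary: pd.DataFrame
    stopped_by_cutoff: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("stored times must be strictly increasing")
        s = self.summary
        if not {"t_s", "tmax_C", "tmin_C", "tmean_C"}.issubset(s.columns):
            raise ValueError("summary must have columns t_s,tmax_C,tmin_C,tmean_C")
        if np.any(s["tmax_C"] + 1e-12 < s["tmean_C"]) or np.any(
            s["tmean_C"] + 1e-12 < s["tmin_C"]
        ):
            raise ValueError("summary must satisfy max >= mean >= min")

    def field_at(self, m: int) -> np.ndarray:
        return self.fields[m]


class _LinearSolver:
    """Direct (splu) for small systems, Jacobi-CG for large ones."""

    def __init__(self, a: sparse.csr_matrix):
        self.n = a.shape[0]
        if self.n <= _DIRECT_SOLVE_MAX:
            self._lu = spla.splu(a.tocsc())
            self._cg = None
        else:
            self._lu = None
            self._a = a
            d = a.diagonal()
            self._m = spla.LinearOperator(a.shape, matvec=lambda x: x / d)

    def solve(self, b: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        if self._lu is not None:
            return self._lu.solve(b)
        x, info = spla.cg(self._a, b, x0=x0, rtol=1e-12, atol=0.0, maxiter=20000, M=self._m)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        return x


def _eddy_field(phantom: Phantom, drive: CoilDrive) -> np.ndarray:
    """Per-voxel eddy heating lattice (W/m^3); zero in air."""
    if drive.field_amplitude == 0:
        return np.zeros(phantom.grid.shape)
    world = phantom.grid.world_grid() * 1e-3  # m
    if drive.axis_point is not None:
        point = np.asarray(drive.axis_point, dtype=float) * 1e-3
    elif phantom.source.sum() > 0:
        w = phantom.source / phantom.source.sum()
        point = np.einsum("ijk,ijkl->l", w, world)
    else:
        point = world.reshape(-1, 3).mean(axis=0)
    rel = world - point
    axial = np.tensordot(rel, drive.axis, axes=([-1], [0]))
    r = np.linalg.norm(rel - axial[..., None] * drive.axis, axis=-1)
    sigma = phantom.property_field("electrical_conductivity")
    mu_r = phantom.property_field("relative_permeability")
    q = sigma * (drive.omega * MU0 * mu_r * drive.field_amplitude) ** 2 * r**2 / 8.0
    q[phantom.labels == AIR] = 0.0
    return q


def _assemble(phantom: Phantom, bcs: BoundaryConditions):
    """Build the conduction operator on solid voxels.

    Returns (solid index map, lumped capacities rho*c_p*V [J/K],
    stiffness K [W/K], robin_rhs [W], dirichlet conductance g_d [W/K]) such
    that the semi-discrete system is

        C dT/dt = -K T + robin_rhs + g_d * T_dirichlet(t) + source_W(t).

    K already contains the Robin and Dirichlet diagonal contributions.
    """
    shape = phantom.grid.shape
    solid = phantom.solid_mask
    n = int(solid.sum())
    index = -np.ones(shape, dtype=np.int64)
    index[solid] = np.arange(n)

    sp_m = phantom.grid.spacing * 1e-3  # m
    vol = float(np.prod(sp_m))
    k_field = phantom.property_field("conductivity")
    rho_cp = phantom.property_field("volumetric_heat_capacity")
    cap = rho_cp[solid] * vol

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    robin_rhs = np.zeros(n)
    g_dir = np.zeros(n)

    for ax in range(3):
        d = sp_m[ax]
        area = vol / d
        # interior faces between voxel pairs along this axis
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        a_solid = solid[tuple(sl_a)]
        b_solid = solid[tuple(sl_b)]
        both = a_solid & b_solid
        ka = k_field[tuple(sl_a)][both]
        kb = k_field[tuple(sl_b)][both]
        kh = 2 * ka * kb / (ka + kb)  # harmonic mean across interfaces
        g = kh * area / d
        ia = index[tuple(sl_a)][both]
        ib = index[tuple(sl_b)][both]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-g, -g])
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)

        # solid/air faces -> Robin (exposed surfaces)
        for sl_s, sl_o in ((sl_a, sl_b), (sl_b, sl_a)):
            exposed = solid[tuple(sl_s)] & ~solid[tuple(sl_o)]
            ii = index[tuple(sl_s)][exposed]
            np.add.at(diag, ii, bcs.h * area)
            np.add.at(robin_rhs, ii, bcs.h * area * bcs.t_infinity)

        # domain-boundary faces
        for side, k_bnd in ((0, slice(0, 1)), (1, slice(-1, None))):
            sl = [slice(None)] * 3
            sl[ax] = k_bnd
            bnd_solid = solid[tuple(sl)]
            ii = index[tuple(sl)][bnd_solid]
            kk = k_field[tuple(sl)][bnd_solid]
            if ax == 2 and side == 1:
                # top face of the grid: exposed, Robin
                np.add.at(diag, ii, bcs.h * area)
                np.add.at(robin_rhs, ii, bcs.h * area * bcs.t_infinity)
            elif bcs.has_dirichlet:
                # five non-top cuboid faces: uniform Dirichlet (ghost at d/2)
                g = kk * area / (d / 2)
                np.add.at(diag, ii, g)
                np.add.at(g_dir, ii, g)
            # otherwise insulated: zero flux, nothing to add

    rows = np.concatenate(rows) if rows else np.empty(0, dtype=int)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
    vals = np.concatenate(vals) if vals else np.empty(0)
    k_mat = sparse.coo_matrix(
        (np.concatenate([vals, diag]), (np.concatenate([rows, np.arange(n)]),
                                        np.concatenate([cols, np.arange(n)]))),
        shape=(n, n),
    ).tocsr()
    return index, cap, k_mat, robin_rhs, g_dir


def solve_transient(
    phantom: Phantom,
    drive: CoilDrive,
    schedule: HeatingSchedule,
    bcs: BoundaryConditions,
    dt: float = 1.0,
    t_end: float = 1800.0,
    store_every: int = 60,
) -> TemperatureSeries:
    """Integrate the phantom temperature field with backward Euler.

    The source at each step is ``s(t_next) * (Q_MNP + Q_eddy)``; the run
    stops early once the tumor volumetric maximum exceeds
    ``schedule.cutoff_temperature`` (if set).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if (
        isinstance(bcs.dirichlet_trace, TimeSeriesTable)
        and bcs.dirichlet_trace.t_end < t_end - 1e-9
    ):
        raise ValueError(
            f"Dirichlet trace ends at {bcs.dirichlet_trace.t_end} s "
            f"but the run extends to {t_end} s"
        )
    index, cap, k_mat, robin_rhs, g_dir = _assemble(phantom, bcs)
    n = len(cap)
    solid = phantom.solid_mask
    vol = float(np.prod(phantom.grid.spacing * 1e-3))
    q_mnp = phantom.source[solid] * vol  # W per voxel
    q_eddy = _eddy_field(phantom, drive)[solid] * vol
    source_w = q_mnp + q_eddy

    tumor_in_solid = phantom.tumor_mask[solid]
    if not tumor_in_solid.any():
        raise ValueError("phantom has no tumor voxels")

    if np.isscalar(bcs.initial_temperature):
        temp = np.full(n, float(bcs.initial_temperature))
    else:
        init = np.asarray(bcs.initial_temperature, dtype=float)
        temp = init[solid] if init.shape == phantom.grid.shape else init.copy()
        if temp.shape != (n,):
            raise ValueError("initial temperature field has the wrong shape")

    a_mat = sparse.diags(cap / dt) + k_mat
    solver = _LinearSolver(a_mat.tocsr())

    def to_lattice(v: np.ndarray) -> np.ndarray:
        out = np.full(phantom.grid.shape, np.nan)
        out[solid] = v
        return out

    def tumor_stats(v: np.ndarray, t: float) -> dict:
        tv = v[tumor_in_solid]
        return {
            "t_s": t,
            "tmax_C": float(tv.max()),
            "tmin_C": float(tv.min()),
            "tmean_C": float(tv.mean()),
        }

    times = [0.0]
    fields = [to_lattice(temp)]
    rows = [tumor_stats(temp, 0.0)]
    stopped = False
    n_steps = int(round(t_end / dt))
    for step in range(1, n_steps + 1):
        t_next = step * dt
        s = schedule_factor(schedule, t_next)
        rhs = cap / dt * temp + robin_rhs + s * source_w
        if bcs.has_dirichlet:
            rhs = rhs + g_dir * bcs.dirichlet_at(t_next)
        temp = solver.solve(rhs, x0=temp)
        if not np.all(np.isfinite(temp)):
            raise FloatingPointError(
                f"non-finite temperatures at t={t_next} s (dt={dt}, step {step})"
            )
        rows.append(tumor_stats(temp, t_next))
        if step % store_every == 0 or step == n_steps:
            times.append(t_next)
            fields.append(to_lattice(temp))
        cutoff = schedule.cutoff_temperature
        if cutoff is not None and rows[-1]["tmax_C"] > cutoff:
            stopped = True
            if times[-1] != t_next:
                times.append(t_next)
                fields.append(to_lattice(temp))
            break
    return TemperatureSeries(
        np.array(times),
        np.stack(fields),
        pd.DataFrame(rows),
        stopped_by_cutoff=stopped,
    )


def solve_steady_dirichlet(
    conductivity: np.ndarray | float,
    source: np.ndarray,
    spacing_mm,
    boundary_value,
) -> np.ndarray:
    """Steady conduction -div(k grad T) = Q on a box with Dirichlet faces.

    ``boundary_value`` is a callable mapping world points (m, at ghost face
    centers) to temperatures, or a scalar.  Used for closed-form
    verification problems (e.g. the uniformly heated sphere).
    """
    source = np.asarray(source, dtype=float)
    shape = source.shape
    sp_m = np.asarray(spacing_mm, dtype=float) * 1e-3
    vol = float(np.prod(sp_m))
    k_field = np.broadcast_to(np.asarray(conductivity, dtype=float), shape)
    n = source.size
    index = np.arange(n).reshape(shape)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs = source.ravel() * vol

    bval = boundary_value if callable(boundary_value) else (lambda pts: np.full(len(pts), float(boundary_value)))

    centers = [np.arange(s) * d for s, d in zip(shape, sp_m)]
    for ax in range(3):
        d = sp_m[ax]
        area = vol / d
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        ka = k_field[tuple(sl_a)].ravel()
        kb = k_field[tuple(sl_b)].ravel()
        g = (2 * ka * kb / (ka + kb)) * area / d
        ia = index[tuple(sl_a)].ravel()
        ib = index[tuple(sl_b)].ravel()
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-g, -g])
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)

        for side in (0, 1):
            sl = [slice(None)] * 3
            sl[ax] = slice(0, 1) if side == 0 else slice(-1, None)
            ii = index[tuple(sl)].ravel()
            kk = k_field[tuple(sl)].ravel()
            g = kk * area / (d / 2)
            # ghost face-center world coordinates
            grids = np.meshgrid(*centers, indexing="ij")
            pts = np.stack([g_.ravel() for g_ in grids], axis=1)[ii]
            pts[:, ax] += (-d / 2) if side == 0 else (d / 2)
            tb = np.asarray(bval(pts), dtype=float)
            diag[ii] += g
            np.add.at(rhs, ii, g * tb)

    a_mat = sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (np.concatenate(rows + [np.arange(n)]), np.concatenate(cols + [np.arange(n)])),
        ),
        shape=(n, n),
    ).tocsr()
    temp = _LinearSolver(a_mat).solve(rhs, x0=np.zeros(n))
    return temp.reshape(shape)


def summarize(series: TemperatureSeries, mask: Mask | np.ndarray) -> pd.DataFrame:
    """Per-stored-time max/min/mean over the masked voxels."""
    m = mask.values if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    if m.shape != series.fields.shape[1:]:
        raise ValueError("mask shape does not match stored fields")
    if not m.any():
        raise ValueError("mask is empty")
    rows = []
    for t, f in zip(series.times, series.fields):
        v = f[m]
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("mask covers only air voxels")
        rows.append(
            {"t_s": float(t), "tmax_C": float(v.max()),
             "tmin_C": float(v.min()), "tmean_C": float(v.mean())}
        )
    return pd.DataFrame(rows)
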