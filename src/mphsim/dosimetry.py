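"""Pre-treatment dose arithmetic, AMF safety screening and CEM43 dosimetry.

Dose planning models the injected nanoparticles as a uniformly heated
sphere of radius R in tissue of conductivity k.  At steady state the
surface-to-far-field temperature rise is dT = q_v R^2 / (3k) with
q_v = SLP * c, which inverts to the minimum iron concentration

    c = 3 dT k / (SLP R^2)        [g/m^3; reported in mg Fe/mL].

Thermal dose uses the Sapareto-Dewey cumulative-equivalent-minutes metric,

    CEM43 = sum_i (dt_i / 60) * R^(43 - T_i),

with R = 0.5 at or above the breakpoint and 0.25 below it (43 C default;
the ~42.5 C human breakpoint is exposed as a parameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .physics import MU0, TemperatureSeries

__all__ = [
    "HERGT_DUTZ_LIMIT",
    "ThermalDose",
    "minimum_concentration",
    "injection_volume",
    "hergt_dutz_product",
    "flux_density_to_field",
    "cem43",
]

HERGT_DUTZ_LIMIT = 5e9  # A/(m s), biological H*f exposure bound


def minimum_concentration(
    delta_t: float, k: float, slp: float, radius: float
) -> float:
    """Minimum iron concentration (mg Fe/mL) for a target temperature rise.

    Parameters
    ----------
    delta_t : target rise, K.
    k : tissue thermal conductivity, W/(m K).
    slp : specific loss power, W/g Fe.
    radius : sphere (tumor) radius, m.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be nonnegative")
    if min(k, slp, radius) <= 0:
        raise ValueError("k, slp and radius must be positive")
    c_g_per_m3 = 3.0 * delta_t * k / (slp * radius**2)
    return c_g_per_m3 / 1000.0  # g/m^3 -> mg/mL


def injection_volume(
    tumor_volume: float, target_concentration: float, stock_concentration: float
) -> float:
    """Injection volume (uL) for a target intratumor concentration.

    ``tumor_volume`` in mm^3 (1 mm^3 = 1 uL); concentrations in mg Fe/mL.
    """
    if stock_concentration <= 0:
        raise ValueError("stock concentration must be positive")
    if target_concentration < 0:
        raise ValueError("target concentration must be nonnegative")
    if target_concentration > stock_concentration:
        warnings.warn(
            "target concentration exceeds the undiluted stock; unreachable "
            "with a single injected volume",
            stacklevel=2,
        )
    return tumor_volume * target_concentration / stock_concentration


def hergt_dutz_product(
    h: float, f: float, limit: float = HERGT_DUTZ_LIMIT
) -> tuple[float, bool]:
    """H*f exposure product (A/(m s)) and whether it passes the safety limit."""
    if h < 0 or f < 0:
        raise ValueError("H and f must be nonnegative")
    product = h * f
    return product, product <= limit


def flux_density_to_field(b_mT: float) -> float:
    """Peak flux density (mT, vacuum) -> peak field amplitude H (A/m)."""
    return b_mT * 1e-3 / MU0


@dataclass
class ThermalDose:
    """Accumulated CEM43 (minutes) with the convention that produced it."""

    cem43: float | np.ndarray  # scalar for a trace, lattice for a field stack
    breakpoint: float = 43.0
    r_above: float = 0.5
    r_below: float = 0.25

    @property
    def is_field(self) -> bool:
        return isinstance(self.cem43, np.ndarray) and np.ndim(self.cem43) > 0


def _cem43_increments(temps: np.ndarray, dt: float, breakpoint, r_above, r_below):
    r = np.where(temps >= breakpoint, r_above, r_below)
    return (dt / 60.0) * np.power(r, 43.0 - temps)


def cem43(
    trace_or_series,
    dt: float | None = None,
    breakpoint: float = 43.0,
    r_above: float = 0.5,
    r_below: float = 0.25,
) -> ThermalDose:
    """Sapareto-Dewey thermal dose from a temperature history.

    Accepts a 1D temperature array (deg C, uniform spacing ``dt`` seconds),
    or a :class:`TemperatureSeries` — in which case the per-voxel dose is
    accumulated over the stored lattices with trapezoid-implied intervals.
    """
    if not 0 < r_above < 1 or not 0 < r_below < 1:
        raise ValueError("R factors must lie in (0, 1)")
    if isinstance(trace_or_series, TemperatureSeries):
        series = trace_or_series
        times = series.times
        fields = series.fields
        dose = np.zeros(fields.shape[1:])
        # each stored lattice covers the interval back to the previous one
        for m in range(1, len(times)):
            seg = times[m] - times[m - 1]
            inc = _cem43_increments(
                np.nan_to_num(fields[m], nan=0.0), seg, breakpoint, r_above, r_below
            )
            dose += np.where(np.isfinite(fields[m]), inc, 0.0)
        return ThermalDose(dose, breakpoint, r_above, r_below)
    temps = np.asarray(trace_or_series, dtype=float)
    if dt is None or dt <= 0:
        raise ValueError("dt (seconds) must be positive for a plain trace")
    total = float(
        _cem43_increments(temps, dt, breakpoint, r_above, r_below).sum()
    )
    return ThermalDose(total, breakpoint, r_above, r_below)


def cem43_from_summary(
    summary, column: str = "tmean_C", breakpoint: float = 43.0,
    r_above: float = 0.5, r_below: float = 0.25,
) -> float:
    """CEM43 from a solver summary table (t_s plus temperature columns)."""
    t = summary["t_s"].to_numpy(float)
    temps = summary[column].to_numpy(float)
    total = 0.0
    for m in range(1, len(t)):
        seg = t[m] - t[m - 1]
        r = r_above if temps[m] >= breakpoint else r_below
        total += (seg / 60.0) * r ** (43.0 - temps[m])
    return total


def duty_factor(on_s: float, off_s: float) -> float:
    """Duty fraction on/(on+off), e.g. 60/30 -> 2/3."""
    if on_s <= 0 or off_s < 0:
        raise ValueError("on_s must be > 0 and off_s >= 0")
    return on_s / (on_s + off_s)
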