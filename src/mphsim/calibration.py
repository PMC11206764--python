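"""Tracer-signal calibration and specific-loss-power (SLP) estimation.

Two fits live here:

1. The serial-dilution calibration.  Samples of known iron concentration
   c (mg Fe/mL) are imaged; the per-sample maximum grayscale value (GV) is
   regressed against the estimated volumetric thermal output
   Q = SLP * c (with 1 mg/mL = 1000 g/m^3, so Q is in W/m^3):

       GV = intercept + slope * Q

   Ordinary least squares with Student-t 95% confidence half-widths.  The
   inverse map Q = (GV - intercept)/slope, clamped at zero, converts tracer
   images to volumetric heat sources.

2. The non-adiabatic lumped-mass pulse fit.  A sample of heat capacity C
   (J/K) containing m_Fe grams of iron is driven by a duty-cycled field;
   its temperature obeys

       C dT/dt = P * chi_on(t) - L (T - T_amb)

   with P the absorbed power (W) and L a linear loss coefficient (W/K).
   Both are fitted by least squares on the closed-form piecewise
   exponential; SLP = P / m_Fe.  Per-pulse refits of P (at the global L)
   give the spread reported as the uncertainty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .imaging_io import VoxelImage

__all__ = [
    "CalibrationSample",
    "CalibrationCurve",
    "PulseTrace",
    "SLPEstimate",
    "fit_calibration",
    "gv_to_power",
    "estimate_slp",
    "read_calibration_csv",
]

MG_PER_ML_TO_G_PER_M3 = 1000.0  # 1 mg/mL == 1 g/L == 1000 g/m^3


@dataclass
class CalibrationSample:
    """One serial-dilution sample: concentration plus replicate max GVs."""

    concentration: float  # mg Fe / mL
    replicate_max_gv: Sequence[float]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        self.replicate_max_gv = np.asarray(self.replicate_max_gv, dtype=float)
        if self.replicate_max_gv.size < 1:
            raise ValueError("at least one replicate is required")

    @property
    def mean_gv(self) -> float:
        return float(np.mean(self.replicate_max_gv))


@dataclass
class CalibrationCurve:
    """Fitted linear map GV = intercept + slope * Q (Q in W/m^3)."""

    slope: float  # GV per (W/m^3)
    intercept: float  # GV at zero power
    r_squared: float
    ci_slope: float = 0.0  # 95% half-widths
    ci_intercept: float = 0.0
    slp_used: float = float("nan")  # W/g, used to build the abscissa

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.ci_slope < 0 or self.ci_intercept < 0:
            raise ValueError("CI half-widths must be nonnegative")

    def power_from_gv(self, gv):
        """Inverse map, clamped below at zero (GV <= intercept -> no heat)."""
        return np.maximum((np.asarray(gv, dtype=float) - self.intercept) / self.slope, 0.0)

    def gv_from_power(self, q):
        return self.intercept + self.slope * np.asarray(q, dtype=float)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        return cls(**json.loads(Path(path).read_text()))


def fit_calibration(
    samples: Sequence[CalibrationSample], slp: float
) -> CalibrationCurve:
    """Ordinary least-squares calibration fit over serial dilutions.

    The abscissa for each sample is its estimated volumetric thermal output
    ``slp * concentration`` in W/m^3; the ordinate is the replicate-mean
    maximum GV.  SLP is assumed concentration-independent.
    """
    if slp <= 0:
        raise ValueError("slp must be positive")
    conc = np.array([s.concentration for s in samples], dtype=float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need >=3 distinct concentrations for a meaningful fit")
    x = slp * conc * MG_PER_ML_TO_G_PER_M3  # W/m^3
    y = np.array([s.mean_gv for s in samples], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in thermal output; fit is degenerate")
    res = stats.linregress(x, y)
    n = len(x)
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else float("inf")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ci_slope=float(tcrit * res.stderr),
        ci_intercept=float(tcrit * res.intercept_stderr),
        slp_used=float(slp),
    )


def gv_to_power(image: VoxelImage, curve: CalibrationCurve) -> VoxelImage:
    """Convert a tracer image from GV to volumetric thermal output (W/m^3)."""
    return image.copy_with(curve.power_from_gv(image.values))


def read_calibration_csv(path) -> list[CalibrationSample]:
    """CSV columns: concentration_mg_per_ml, replicate, max_gv."""
    df = pd.read_csv(path)
    required = {"concentration_mg_per_ml", "replicate", "max_gv"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibration CSV must have columns {sorted(required)}")
    return [
        CalibrationSample(conc, grp["max_gv"].to_numpy(float))
        for conc, grp in df.groupby("concentration_mg_per_ml")
    ]


# ---- pulse calorimetry -------------------------------------------------


@dataclass
class PulseTrace:
    """Duty-cycled calorimetry trace of a nanoparticle sample.

    ``schedule`` is a list of (t_start, t_stop) ON intervals in seconds;
    the field is OFF outside them.
    """

    times: np.ndarray  # s
    temperatures: np.ndarray  # deg C
    schedule: Sequence[tuple[float, float]]
    fe_mass: float  # g Fe
    heat_capacity: float  # J/K of sample + holder
    ambient: float  # deg C

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fe_mass <= 0:
            raise ValueError("fe_mass must be positive")
        if self.heat_capacity <= 0:
            raise ValueError("heat_capacity must be positive")
        self.schedule = [(float(a), float(b)) for a, b in self.schedule]
        for a, b in self.schedule:
            if b <= a:
                raise ValueError("schedule intervals must have t_stop > t_start")

    def on_indicator(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        on = np.zeros_like(t, dtype=bool)
        for a, b in self.schedule:
            on |= (t >= a) & (t < b)
        return on


@dataclass
class SLPEstimate:
    """Result of the lumped-mass pulse fit."""

    slp: float  # W/g
    slp_std: float  # W/g, spread of per-pulse estimates
    power: float  # W
    loss_coefficient: float  # W/K
    per_pulse: np.ndarray = field(default_factory=lambda: np.empty(0))
    negative_power_flag: bool = False


def _simulate_lumped(
    times: np.ndarray,
    schedule: Sequence[tuple[float, float]],
    power: float,
    loss: float,
    heat_capacity: float,
    ambient: float,
    t0_temperature: float,
) -> np.ndarray:
    """Exact piecewise-exponential solution of C dT/dt = P*chi - L(T-Ta).

    Integrates between the supplied sample times, splitting steps at
    schedule edges so switching instants are handled exactly.
    """
    edges = sorted({a for a, _ in schedule} | {b for _, b in schedule})
    knots = np.unique(np.concatenate([times, np.asarray(edges, dtype=float)]))
    knots = knots[(knots >= times[0]) & (knots <= times[-1])]
    temp = np.empty_like(knots)
    temp[0] = t0_temperature
    on_mid = np.zeros(len(knots) - 1, dtype=bool)
    mids = 0.5 * (knots[:-1] + knots[1:])
    for a, b in schedule:
        on_mid |= (mids >= a) & (mids < b)
    for i in range(len(knots) - 1):
        dt = knots[i + 1] - knots[i]
        p = power if on_mid[i] else 0.0
        if loss > 1e-15:
            t_inf = ambient + p / loss
            temp[i + 1] = t_inf + (temp[i] - t_inf) * np.exp(-loss * dt / heat_capacity)
        else:
            temp[i + 1] = temp[i] + p * dt / heat_capacity
    return np.interp(times, knots, temp)


def estimate_slp(trace: PulseTrace) -> SLPEstimate:
    """Fit the non-adiabatic lumped model to a pulse train and return SLP.

    A global (P, L) fit over the whole trace gives the point estimate; P is
    then refitted per ON pulse at the global L, and the standard deviation
    of the per-pulse SLPs is reported as the uncertainty.
    """
    if not trace.schedule:
        raise ValueError("trace schedule contains no ON interval")
    in_range = [
        (a, b)
        for a, b in trace.schedule
        if a < trace.times[-1] and b > trace.times[0]
    ]
    if not in_range:
        raise ValueError("no ON interval overlaps the recorded trace")

    t0_temp = float(trace.temperatures[0])

    def residuals(params):
        p, logl = params
        model = _simulate_lumped(
            trace.times, trace.schedule, p, np.exp(logl),
            trace.heat_capacity, trace.ambient, t0_temp,
        )
        return model - trace.temperatures

    # initial P from the first ON pulse's mean heating rate; L small
    a, b = in_range[0]
    sel = (trace.times >= a) & (trace.times <= b)
    if sel.sum() >= 2:
        slope0 = np.polyfit(trace.times[sel], trace.temperatures[sel], 1)[0]
    else:
        slope0 = 0.0
    p0 = max(slope0 * trace.heat_capacity, 1e-6)
    fit = optimize.least_squares(
        residuals, x0=[p0, np.log(1e-4)], method="lm", max_nfev=2000
    )
    power, loss = float(fit.x[0]), float(np.exp(fit.x[1]))

    # per-pulse refits of P at the global L
    per_pulse = []
    for a, b in in_range:
        sel = (trace.times >= a) & (trace.times <= b)
        if sel.sum() < 3:
            continue
        tseg = trace.times[sel]
        yseg = trace.temperatures[sel]

        def seg_resid(p, tseg=tseg, yseg=yseg, a=a, b=b):
            model = _simulate_lumped(
                tseg, [(a, b)], p[0], loss,
                trace.heat_capacity, trace.ambient, float(yseg[0]),
            )
            return model - yseg

        segfit = optimize.least_squares(seg_resid, x0=[max(power, 1e-6)], method="lm")
        per_pulse.append(segfit.x[0] / trace.fe_mass)
    per_pulse = np.asarray(per_pulse)

    slp = power / trace.fe_mass
    slp_std = float(np.std(per_pulse, ddof=1)) if len(per_pulse) > 1 else 0.0
    return SLPEstimate(
        slp=float(slp),
        slp_std=slp_std,
        power=power,
        loss_coefficient=loss,
        per_pulse=per_pulse,
        negative_power_flag=power < 0,
    )
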