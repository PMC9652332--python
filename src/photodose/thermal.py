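"""First-order lumped thermal model of sample-well heating.

Illumination warms the well contents (mostly via absorption in the plate
material) toward an irradiance-dependent steady state; removing the light
relaxes it back to ambient.  A single-compartment Newtonian model captures
the measured behaviour:

    T(t)    = T_inf - (T_inf - T_env) * exp(-t / tau)
    T_inf   = T_env + gain(I) * I

The steady-state rise is *not* proportional to irradiance in the measured
system (rises of 15.6 degC at 100 mW/cm^2 but 28.8 degC at 200 mW/cm^2
from a 20.2 degC room), so ``gain`` is a per-irradiance table interpolated
linearly rather than a single coefficient.

The time constant tau is not directly reported; the default is anchored to
the observed 37 degC crossing 13 min into a 200 mW/cm^2 run, which gives
tau = 780 s / ln((49.0-20.2)/(49.0-37.0)) ~= 891 s.  All tau-dependent
outputs are model-relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ThermalParams",
    "temperature_at",
    "steady_state",
    "time_to_threshold",
    "max_safe_plan",
    "fit_thermal_curve",
    "DEFAULT_TAU_S",
]

#: Default time constant anchored to the 37 degC crossing at 780 s under
#: 200 mW/cm^2 with T_env = 20.2 degC and T_inf = 49.0 degC.
DEFAULT_TAU_S: float = 780.0 / math.log((49.0 - 20.2) / (49.0 - 37.0))


@dataclass(frozen=True)
class ThermalParams:
    """Ambient temperature, per-irradiance steady-state gain table
    (degC.cm^2/mW, interpolated linearly and clamped at the table ends)
    and the relaxation time constant."""

    t_env_C: float = 20.2
    gain_table: tuple[tuple[float, float], ...] = (
        # (irradiance mW/cm^2, gain degC.cm^2/mW) from the measured
        # steady states: 35.8 degC at 100, 49.0 degC at 200
        (100.0, (35.8 - 20.2) / 100.0),
        (200.0, (49.0 - 20.2) / 200.0),
    )
    tau_s: float = DEFAULT_TAU_S

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau must be positive")
        irr = [i for i, _ in self.gain_table]
        if len(irr) < 1 or any(g < 0 for _, g in self.gain_table):
            raise ValueError("gain table must be non-empty with non-negative gains")
        if sorted(irr) != irr:
            raise ValueError("gain table must be sorted by irradiance")

    def gain(self, irradiance_mWcm2: float) -> float:
        irr = np.array([i for i, _ in self.gain_table])
        g = np.array([v for _, v in self.gain_table])
        return float(np.interp(irradiance_mWcm2, irr, g))

    @classmethod
    def from_steady_states(cls, t_env_C: float,
                           steady: dict[float, float],
                           tau_s: float = DEFAULT_TAU_S) -> "ThermalParams":
        """Build the gain table from observed (irradiance -> steady-state
        temperature) pairs."""
        table = tuple(sorted((i, (t - t_env_C) / i) for i, t in steady.items()))
        return cls(t_env_C=t_env_C, gain_table=table, tau_s=tau_s)


def steady_state(irradiance_mWcm2: float, p: ThermalParams) -> float:
    """T_inf = T_env + gain(I) * I (degC)."""
    if irradiance_mWcm2 < 0:
        raise ValueError("irradiance must be non-negative")
    return p.t_env_C + p.gain(irradiance_mWcm2) * irradiance_mWcm2


def temperature_at(t_s, irradiance_mWcm2: float, p: ThermalParams):
    """Sample temperature ``t_s`` seconds into a constant-irradiance
    exposure that starts from ambient."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    t_inf = steady_state(irradiance_mWcm2, p)
    out = t_inf - (t_inf - p.t_env_C) * np.exp(-t / p.tau_s)
    return float(out) if out.ndim == 0 else out


def time_to_threshold(irradiance_mWcm2: float, t_thresh_C: float,
                      p: ThermalParams) -> float:
    """Seconds until the sample first reaches ``t_thresh_C``.

    Returns 0 when the threshold is at or below ambient and ``math.inf``
    ("never") when the steady state never reaches it.
    """
    if t_thresh_C <= p.t_env_C:
        return 0.0
    t_inf = steady_state(irradiance_mWcm2, p)
    if t_inf <= t_thresh_C:
        return math.inf
    return p.tau_s * math.log((t_inf - p.t_env_C) / (t_inf - t_thresh_C))


@dataclass(frozen=True)
class SafePlanResult:
    irradiance_mWcm2: float
    duty: float
    exposure_s: float
    peak_temp_C: float


def max_safe_plan(dose_Jcm2: float, t_thresh_C: float, p: ThermalParams,
                  calib, pwm_cfg=None, *,
                  criterion: str = "exposure") -> SafePlanResult | None:
    """Highest achievable irradiance level whose full exposure for the
    dose stays below the temperature threshold.

    Scans the duty-quantised irradiance levels from the calibration in
    descending order; returns ``None`` when no level is safe.
    ``criterion='exposure'`` (default) checks the temperature reached at
    the end of the finite exposure; ``criterion='steady_state'`` demands
    the level be safe under indefinite illumination (T_inf below the
    threshold), the conservative choice for back-to-back plate runs.
    """
    from .pwm import PwmConfig, available_duties, exposure_time

    if dose_Jcm2 < 0:
        raise ValueError("dose must be non-negative")
    if criterion not in ("exposure", "steady_state"):
        raise ValueError(f"unknown criterion {criterion!r}")
    pwm_cfg = pwm_cfg or PwmConfig()
    duties = available_duties(pwm_cfg)
    levels = np.atleast_1d(calib.irradiance_for_duty(duties))
    for duty, level in sorted(zip(duties, levels), key=lambda x: -x[1]):
        if level <= 0:
            continue
        if dose_Jcm2 == 0:
            return SafePlanResult(float(level), float(duty), 0.0, p.t_env_C)
        t_exp = exposure_time(dose_Jcm2, level)
        peak = (steady_state(level, p) if criterion == "steady_state"
                else temperature_at(t_exp, level, p))
        if peak < t_thresh_C:
            return SafePlanResult(float(level), float(duty), t_exp, float(peak))
    return None


def fit_thermal_curve(t_s, temp_C, irradiance_mWcm2: float,
                      t_env_C: float) -> ThermalParams:
    """Recover (gain at this irradiance, tau) from a measured warming
    curve by nonlinear least squares."""
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(temp_C, dtype=float)

    def model(t, d_inf, tau):
        return t_env_C + d_inf * (1.0 - np.exp(-t / tau))

    d0 = max(y.max() - t_env_C, 1.0)
    (d_inf, tau), _ = curve_fit(model, t, y, p0=[d0, max(t.max() / 3.0, 1.0)])
    gain = d_inf / irradiance_mWcm2
    return ThermalParams(t_env_C=t_env_C,
                         gain_table=((irradiance_mWcm2, gain),),
                         tau_s=float(tau))
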