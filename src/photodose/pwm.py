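"""Pulse-width-modulation irradiance control.

The LED array runs at a fixed supply voltage; average irradiance is set by
chopping the drive with a square wave whose duty cycle the DAQ synthesises
sample-by-sample.  With the default 250 Hz carrier and 5 kHz analog-output
sample rate each period holds 20 samples, so the duty cycle — and hence the
irradiance, which is linear in duty — is adjustable in 5 % steps giving 20
nonzero levels.

A measured duty -> irradiance calibration (least-squares line through the
recorded points, or an interpolating lookup table when phototransistor-style
saturation makes the top of the range bend) converts a target irradiance to
the nearest representable duty; ties break toward the *lower* duty because
under-dosing is the safer failure mode in a cytotoxicity assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PwmConfig",
    "IrradianceCalibration",
    "samples_per_period",
    "available_duties",
    "duty_for_irradiance",
    "exposure_time",
    "build_waveform",
]


@dataclass(frozen=True)
class PwmConfig:
    """Carrier/sampling rates and drive levels of the PWM channel."""

    carrier_hz: float = 250.0
    sample_hz: float = 5000.0
    high_level_V: float = 10.0
    low_level_V: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0 or self.sample_hz <= 0:
            raise ValueError("rates must be positive")
        if self.high_level_V <= self.low_level_V:
            raise ValueError("high level must exceed low level")


def samples_per_period(cfg: PwmConfig) -> int:
    """Number of output samples per carrier period (sample_hz / carrier_hz)."""
    ratio = cfg.sample_hz / cfg.carrier_hz
    n = round(ratio)
    if abs(ratio - n) > 1e-9 or n < 1:
        raise ValueError(
            f"sample rate {cfg.sample_hz} Hz is not an integer multiple of the "
            f"carrier {cfg.carrier_hz} Hz (ratio {ratio:.4g})")
    return int(n)


def available_duties(cfg: PwmConfig) -> np.ndarray:
    """The representable nonzero duty fractions k/N, k = 1..N."""
    n = samples_per_period(cfg)
    return np.arange(1, n + 1) / n


@dataclass
class IrradianceCalibration:
    """Duty -> irradiance map from powermeter measurements.

    ``mode='linear'`` fits a least-squares line (intercept allowed) through
    the points; ``mode='table'`` interpolates them directly, for when high
    duties sag below the line.  ``max_irradiance`` defaults to the
    calibrated value at duty 1.
    """

    points: list[tuple[float, float]]
    mode: str = "linear"
    slope: float = field(init=False)
    intercept: float = field(init=False)
    max_irradiance: float = field(init=False)
    fit_residual: float = field(init=False)

    def __post_init__(self) -> None:
        pts = sorted((float(d), float(e)) for d, e in self.points)
        if len(pts) < 2:
            raise ValueError("calibration needs at least two points")
        d = np.array([p[0] for p in pts])
        e = np.array([p[1] for p in pts])
        if np.any((d < 0) | (d > 1)):
            raise ValueError("duty fractions must lie in [0, 1]")
        if np.any(e < 0) or np.any(np.diff(e) < 0):
            raise ValueError("irradiance must be non-negative and non-decreasing in duty")
        if self.mode not in ("linear", "table"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        self._d, self._e = d, e
        if len(pts) == 2:  # exact two-point line; polyfit rounds
            self.slope = (e[1] - e[0]) / (d[1] - d[0])
            self.intercept = e[0] - self.slope * d[0]
        else:
            self.slope, self.intercept = np.polyfit(d, e, 1)
        self.fit_residual = float(np.max(np.abs(np.polyval([self.slope, self.intercept], d) - e)))
        self.max_irradiance = float(self.irradiance_for_duty(1.0))

    @classmethod
    def linear(cls, slope: float, intercept: float = 0.0) -> "IrradianceCalibration":
        """Ideal linear calibration (convenience for planning/simulation)."""
        return cls(points=[(0.0, intercept), (1.0, slope + intercept)])

    @classmethod
    def from_csv(cls, path, mode: str = "linear") -> "IrradianceCalibration":
        import pandas as pd
        df = pd.read_csv(path, comment="#")
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: expected columns (duty, irradiance_mWcm2)")
        return cls(points=list(zip(df[cols[0]].astype(float),
                                   df[cols[1]].astype(float))), mode=mode)

    def irradiance_for_duty(self, duty) -> np.ndarray | float:
        duty = np.asarray(duty, dtype=float)
        if self.mode == "linear":
            out = self.slope * duty + self.intercept
        else:
            out = np.interp(duty, self._d, self._e)
        out = np.maximum(out, 0.0)
        return float(out) if out.ndim == 0 else out


def duty_for_irradiance(target_mWcm2: float, calib: IrradianceCalibration,
                        cfg: PwmConfig) -> tuple[float, float]:
    """The representable duty whose calibrated irradiance is nearest the
    target, with ties broken toward the lower duty.

    Returns ``(duty, achieved_mWcm2)``.
    """
    if target_mWcm2 <= 0:
        raise ValueError("target irradiance must be positive")
    if target_mWcm2 > calib.max_irradiance:
        raise ValueError(
            f"target {target_mWcm2:g} mW/cm^2 exceeds calibrated maximum "
            f"{calib.max_irradiance:g} mW/cm^2")
    duties = available_duties(cfg)
    achieved = np.atleast_1d(calib.irradiance_for_duty(duties))
    diff = np.abs(achieved - target_mWcm2)
    # lowest duty among all candidates within a rounding tolerance of the
    # best match — duties ascend, so the first such index is the tie-break
    tol = 1e-9 * max(1.0, abs(target_mWcm2))
    i = int(np.argmax(diff <= diff.min() + tol))
    return float(duties[i]), float(achieved[i])


def exposure_time(dose_Jcm2: float, irradiance_mWcm2: float) -> float:
    """Seconds of illumination for a fluence at a given irradiance:
    dose / (irradiance / 1000)."""
    if dose_Jcm2 <= 0 or irradiance_mWcm2 <= 0:
        raise ValueError("dose and irradiance must be positive")
    return dose_Jcm2 / (irradiance_mWcm2 / 1000.0)


def build_waveform(duty: float, cfg: PwmConfig) -> np.ndarray:
    """One carrier period of output samples: round(duty*N) samples at the
    high level followed by the remainder at the low level."""
    n = samples_per_period(cfg)
    n_high_f = duty * n
    n_high = round(n_high_f)
    if not 0 <= duty <= 1 or abs(n_high_f - n_high) > 1e-9:
        raise ValueError(
            f"duty {duty:g} is not representable with {n} samples per period")
    wave = np.full(n, cfg.low_level_V)
    wave[:n_high] = cfg.high_level_V
    return wave
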