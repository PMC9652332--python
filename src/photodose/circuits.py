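"""On-board sensor circuits and the PCB electrical budget.

The LED-array PCB carries an NTC thermistor and a phototransistor, each
read through a simple voltage divider against a fixed resistor (5 kOhm for
the thermistor, 10 kOhm for the phototransistor) from the 12 V supply.
The divider is oriented with the sensor on the supply side and the output
taken across the fixed resistor, so the output voltage *rises* as the
sensor resistance falls — i.e. with increasing temperature (NTC) or light.

The electrical budget checks the power-distribution design: five series
strings of five LEDs in parallel, the lead voltage drop from trace
geometry, and the equivalent AWG wire gauge of the PCB trace
cross-section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DividerCircuit",
    "NtcModel",
    "ElectricalBudget",
    "divider_output",
    "sensor_resistance_from_voltage",
    "temperature_from_voltage",
    "fit_ntc_beta",
    "fit_phototransistor",
    "electrical_budget",
    "awg_equivalent",
    "relative_drop_pct",
]


@dataclass(frozen=True)
class DividerCircuit:
    """Voltage divider: supply -> sensor -> tap -> fixed resistor -> ground
    (``sensor_on_top=True``, the default), output measured at the tap."""

    supply_V: float = 12.0
    fixed_ohm: float = 5000.0
    sensor_on_top: bool = True

    def __post_init__(self) -> None:
        if self.supply_V <= 0 or self.fixed_ohm <= 0:
            raise ValueError("supply and fixed resistance must be positive")


def divider_output(circuit: DividerCircuit, sensor_ohm: float) -> float:
    """Divider tap voltage for a given sensor resistance."""
    if sensor_ohm <= 0:
        raise ValueError("sensor resistance must be positive")
    frac = (circuit.fixed_ohm / (circuit.fixed_ohm + sensor_ohm)
            if circuit.sensor_on_top
            else sensor_ohm / (circuit.fixed_ohm + sensor_ohm))
    return circuit.supply_V * frac


def sensor_resistance_from_voltage(circuit: DividerCircuit, v: float) -> float:
    if not 0 < v < circuit.supply_V:
        raise ValueError(
            f"voltage {v:g} V outside the open interval (0, {circuit.supply_V:g}) V")
    if circuit.sensor_on_top:
        return circuit.fixed_ohm * (circuit.supply_V - v) / v
    return circuit.fixed_ohm * v / (circuit.supply_V - v)


@dataclass(frozen=True)
class NtcModel:
    """Beta-model NTC thermistor: R(T) = r0 * exp(beta * (1/T - 1/t0)),
    temperatures in kelvin.  Defaults: 10 kOhm at 25 degC, beta 3950 K."""

    r0_ohm: float = 10_000.0
    t0_K: float = 298.15
    beta_K: float = 3950.0

    def __post_init__(self) -> None:
        if min(self.r0_ohm, self.t0_K, self.beta_K) <= 0:
            raise ValueError("NTC parameters must be positive")

    def resistance(self, temp_C: float) -> float:
        t_K = temp_C + 273.15
        return self.r0_ohm * math.exp(self.beta_K * (1.0 / t_K - 1.0 / self.t0_K))

    def temperature_C(self, resistance_ohm: float) -> float:
        if resistance_ohm <= 0:
            raise ValueError("resistance must be positive")
        inv_t = 1.0 / self.t0_K + math.log(resistance_ohm / self.r0_ohm) / self.beta_K
        return 1.0 / inv_t - 273.15


def temperature_from_voltage(v: float, circuit: DividerCircuit,
                             ntc: NtcModel) -> float:
    """Invert divider then beta model: tap voltage -> temperature (degC)."""
    return ntc.temperature_C(sensor_resistance_from_voltage(circuit, v))


def fit_ntc_beta(temps_C, resistances_ohm) -> NtcModel:
    """Recover (r0 at the first point's temperature, beta) by linear
    regression of ln R against 1/T."""
    t = np.asarray(temps_C, dtype=float) + 273.15
    r = np.asarray(resistances_ohm, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two calibration points")
    beta, lnr_at = np.polyfit(1.0 / t - 1.0 / t[0], np.log(r), 1)
    return NtcModel(r0_ohm=float(np.exp(lnr_at)), t0_K=float(t[0]),
                    beta_K=float(beta))


@dataclass(frozen=True)
class LinearSensorFit:
    slope: float
    intercept: float
    max_residual: float  # worst absolute misfit, in the input power unit


def fit_phototransistor(power_mW, voltage_V) -> LinearSensorFit:
    """Least-squares line through phototransistor readings, with the worst
    residual expressed back in optical-power units.

    Phototransistors sag slightly at high power (saturation); the linear
    calibration absorbs most of it and the residual bound records what is
    left, which is the number a bounded-error irradiance contract checks.
    """
    p = np.asarray(power_mW, dtype=float)
    v = np.asarray(voltage_V, dtype=float)
    slope, intercept = np.polyfit(p, v, 1)
    if slope == 0:
        raise ValueError("degenerate phototransistor response")
    resid_power = (v - intercept) / slope - p
    return LinearSensorFit(slope=float(slope), intercept=float(intercept),
                           max_residual=float(np.max(np.abs(resid_power))))


# ---------------------------------------------------------------------------
# electrical budget

#: AWG diameters follow d(n) = 0.127 mm * 92^((36 - n) / 39)
_AWG_RANGE = range(0, 41)


def _awg_area_mm2(n: int) -> float:
    d = 0.127 * 92.0 ** ((36 - n) / 39.0)
    return math.pi * d * d / 4.0


def awg_equivalent(area_mm2: float) -> int:
    """Nearest standard AWG gauge by cross-sectional area; ties go to the
    thinner (higher-number) gauge."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    best = min(_AWG_RANGE, key=lambda n: (abs(_awg_area_mm2(n) - area_mm2), -n))
    return best


@dataclass(frozen=True)
class ElectricalBudget:
    """Array power-distribution parameters: ``n_parallel`` strings of
    ``n_series`` LEDs, per-LED forward voltage/current, and the PCB supply
    trace geometry."""

    n_series: int = 5
    n_parallel: int = 5
    v_led_V: float = 2.4
    i_led_A: float = 0.6
    lead_width_mm: float = 4.0
    copper_height_mm: float = 0.07
    copper_resistivity_ohm_m: float = 1.68e-8  # Cu at 20 degC

    def __post_init__(self) -> None:
        if min(self.n_series, self.n_parallel) < 1:
            raise ValueError("series/parallel counts must be >= 1")
        if min(self.v_led_V, self.i_led_A) <= 0:
            raise ValueError("LED operating point must be positive")


def relative_drop_pct(drop_V: float, series_V: float) -> float:
    """Lead voltage drop as a percentage of the series-string voltage."""
    if series_V <= 0:
        raise ValueError("series voltage must be positive")
    return 100.0 * drop_V / series_V


def electrical_budget(b: ElectricalBudget, lead_length_mm: float) -> dict:
    """Full electrical report for the array supply lead.

    total_A   = n_parallel * i_led
    series_V  = n_series * v_led
    lead_ohm  = rho * L / (w * h);  drop_V = total_A * lead_ohm
    awg_equiv = nearest standard gauge to the trace cross-section w * h
    """
    area_mm2 = b.lead_width_mm * b.copper_height_mm
    if area_mm2 <= 0:
        raise ValueError("trace cross-section area must be positive")
    if lead_length_mm <= 0:
        raise ValueError("lead length must be positive")
    total_A = b.n_parallel * b.i_led_A
    series_V = b.n_series * b.v_led_V
    lead_ohm = (b.copper_resistivity_ohm_m * (lead_length_mm / 1000.0)
                / (area_mm2 * 1e-6))
    drop_V = total_A * lead_ohm
    return {
        "total_A": total_A,
        "series_V": series_V,
        "lead_area_mm2": area_mm2,
        "lead_ohm": lead_ohm,
        "drop_V": drop_V,
        "drop_pct": relative_drop_pct(drop_V, series_V),
        "awg_equiv": awg_equivalent(area_mm2),
    }
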