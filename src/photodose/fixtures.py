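"""Seeded synthetic data emulating the instrument's measured inputs.

Everything the planner and analysis chain consume can be generated here
without hardware: an LED emission spectrum (peaked at 690 nm with
half-maximum crossings at 676 and 702 nm, i.e. a 26 nm FWHM, slightly
asymmetric like a real LED), a photosensitizer Q-band absorption
(~10 nm FWHM centred near 690 nm, the verteporfin-like band), a near-flat
powermeter responsivity, a duty -> irradiance calibration with mild
high-duty saturation, and noisy plate-reader viability tables.

Generation is deterministic per seed; re-running with the same seed
reproduces byte-identical CSV exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate import PlateLayout, Role, canonical_96well_layout
from .pwm import IrradianceCalibration
from .spectra import Spectrum
from .doseresponse import ViabilityTable, four_param_logistic

__all__ = ["FixtureSet", "generate_fixtures", "generate_viability"]

_SQRT_2LN2 = np.sqrt(2.0 * np.log(2.0))


def _skew_gaussian(grid: np.ndarray, peak_nm: float,
                   left_half_nm: float, right_half_nm: float) -> np.ndarray:
    """Two half-Gaussians joined at the peak, with the stated half-maximum
    crossing distances on each side."""
    sigma_l = left_half_nm / _SQRT_2LN2
    sigma_r = right_half_nm / _SQRT_2LN2
    sigma = np.where(grid < peak_nm, sigma_l, sigma_r)
    return np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)


@dataclass
class FixtureSet:
    """The bundle of synthetic instrument inputs for one seed."""

    seed: int
    led_spectrum: Spectrum
    absorber_spectrum: Spectrum
    detector_spectrum: Spectrum
    calibration: IrradianceCalibration
    layout: PlateLayout
    board_config: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        """Export every fixture as plain text (CSV/JSON)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.led_spectrum.to_csv(d / "led_emission.csv",
                                 comment=f"synthetic LED emission, seed {self.seed}")
        self.absorber_spectrum.to_csv(d / "absorber.csv",
                                      comment="synthetic photosensitizer Q-band absorption")
        self.detector_spectrum.to_csv(d / "powermeter_response.csv",
                                      comment="synthetic powermeter responsivity")
        pd.DataFrame(self.calibration.points,
                     columns=["duty", "irradiance_mWcm2"]).to_csv(
            d / "calibration.csv", index=False)
        self.layout.to_json(d / "layout.json")


def generate_fixtures(seed: int = 0) -> FixtureSet:
    """Deterministic synthetic fixture bundle for a given seed."""
    rng = np.random.default_rng(seed)

    grid = np.arange(600.0, 780.0 + 0.25, 0.25)
    led = _skew_gaussian(grid, peak_nm=690.0, left_half_nm=14.0, right_half_nm=12.0)
    # measurement ripple well below the 5 % secondary-peak tolerance
    led = led * (1.0 + 0.002 * rng.standard_normal(grid.size))
    led = np.clip(led, 0.0, None)
    led_spectrum = Spectrum(grid, led)

    # single Q-band, 10 nm FWHM at 690 nm, on a weak sloping baseline that
    # keeps the band the local maximum at the reference line
    band = _skew_gaussian(grid, 690.0, 5.0, 5.0)
    baseline = 0.02 * (1.0 + (780.0 - grid) / 400.0)
    absorber_spectrum = Spectrum(grid, band + baseline)

    # near-flat detector: 3 % tilt across the plotted window
    detector_spectrum = Spectrum(grid, 1.0 + 0.03 * (grid - 690.0) / 100.0)

    # duty -> irradiance: linear at 400 mW/cm^2 full scale with a mild
    # (~1 %) saturation droop at the top and small seeded read noise
    duties = np.arange(1, 21) / 20.0
    irr = 400.0 * duties * (1.0 - 0.01 * duties)
    irr = irr + 0.2 * rng.standard_normal(duties.size)
    irr = np.maximum.accumulate(np.clip(irr, 0.0, None))  # keep monotone
    calibration = IrradianceCalibration(points=list(zip(duties, irr)))

    board_config = {
        "pwm": {"carrier_hz": 250.0, "sample_hz": 5000.0, "high_level_V": 10.0},
        "divider": {"supply_V": 12.0, "thermistor_fixed_ohm": 5000.0,
                    "phototransistor_fixed_ohm": 10000.0},
        "ntc": {"r0_ohm": 10000.0, "t0_C": 25.0, "beta_K": 3950.0},
        "budget": {"n_series": 5, "n_parallel": 5, "v_led_V": 2.4,
                   "i_led_A": 0.6, "lead_width_mm": 4.0,
                   "copper_height_mm": 0.07},
        "daq_ports": {"pwm": "AO0", "thermistor": "AI0",
                      "phototransistor": "AI1",
                      "motor_x": ["p0.1", "p0.2"], "motor_y": ["p0.3", "p0.4"]},
    }

    return FixtureSet(seed=seed, led_spectrum=led_spectrum,
                      absorber_spectrum=absorber_spectrum,
                      detector_spectrum=detector_spectrum,
                      calibration=calibration,
                      layout=canonical_96well_layout(),
                      board_config=board_config)


def generate_viability(layout: PlateLayout | None = None, *,
                       ec50_Jcm2: float = 6.0, hill: float = 2.0,
                       top: float = 100.0, bottom: float = 0.0,
                       cv: float = 0.05, dose_jitter_cv: float = 0.0,
                       lum_0pct: float = 500.0, lum_100pct: float = 10500.0,
                       seed: int = 0) -> ViabilityTable:
    """Synthetic plate-reader table for a treatment layout.

    Per-well viability follows the 4PL ground truth at the group's dose
    (optionally jittered per well by ``dose_jitter_cv`` to emulate
    well-to-well light-dose variation), then multiplicative measurement
    noise of coefficient of variation ``cv`` is applied before mapping to
    raw luminescence between the MO (0 %) and NDNL (100 %) anchors.
    Untreated wells (dose 0, and the light-only LND control which carries
    no drug) sit at the top asymptote, so dose-0 means come out at ~100 %.
    """
    layout = layout or canonical_96well_layout()
    rng = np.random.default_rng(seed)
    rows = []
    for g in layout.groups:
        for w in g.wells:
            if g.role is Role.MO:
                raw = lum_0pct * (1.0 + 0.02 * rng.standard_normal())
                dose = 0.0
            else:
                if g.role is Role.TREATMENT and g.dose_Jcm2 > 0:
                    dose = g.dose_Jcm2
                    d_eff = dose * (1.0 + dose_jitter_cv * rng.standard_normal()) \
                        if dose_jitter_cv > 0 else dose
                    v = four_param_logistic(max(d_eff, 0.0), top, bottom,
                                            ec50_Jcm2, hill)
                else:
                    # DNL/LND/NDNL: no drug-light combination, no kill
                    dose = 0.0
                    v = top
                v = v * (1.0 + cv * rng.standard_normal())
                raw = lum_0pct + v / 100.0 * (lum_100pct - lum_0pct)
            rows.append({"well": w, "group": g.label, "role": g.role.value,
                         "dose_Jcm2": dose, "luminescence": raw})
    return ViabilityTable(pd.DataFrame(rows))
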