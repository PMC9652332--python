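"""Spectrum handling and spectral dosimetry.

LED sources are broader than the diode lasers traditionally used for
photodynamic therapy (PDT), so a given irradiance delivers fewer photons
into the photosensitizer's absorption band than the same irradiance from a
laser tuned to the band peak.  The *spectral efficiency* epsilon quantifies
this: it is the absorption-weighted mean of the source spectrum, normalised
by the absorption at a reference laser line,

    epsilon = [ integral S(l) A(l) dl / integral S(l) dl ] / A(l_ref)

with S the source emission, A the photosensitizer absorption and l_ref the
laser wavelength.  Multiplying a fluence (J/cm^2) by epsilon yields the
*effective light dose* — the laser-equivalent dose, which makes LED and
laser dose-response experiments directly comparable.

A second correction of the same form, computed against the powermeter
responsivity R(l), accounts for the meter reading broadband LED light with
a calibration taken at the laser line.  It is applied to the irradiance
*reading* (reading -> true irradiance) before any fluence is accumulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Spectrum",
    "LaserLine",
    "SpectralEfficiency",
    "fwhm_interval",
    "spectral_efficiency",
    "effective_dose",
    "correct_reading",
]


@dataclass(frozen=True)
class Spectrum:
    """A sampled wavelength -> value curve (emission, absorption or
    detector responsivity), in arbitrary units.

    Wavelengths must be strictly increasing, values non-negative with at
    least one strictly positive sample.  Outside its sampled support a
    spectrum is defined to be zero (physical emission bounds), never
    extrapolated.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise ValueError("wavelengths and values must be 1-D and of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        if not np.any(v > 0):
            raise ValueError("spectrum is identically zero")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def __call__(self, grid_nm) -> np.ndarray:
        """Evaluate by linear interpolation; zero outside the support."""
        return np.interp(np.asarray(grid_nm, dtype=float),
                         self.wavelengths_nm, self.values,
                         left=0.0, right=0.0)

    def resample(self, grid_nm) -> "Spectrum":
        """Return the spectrum sampled on exactly ``grid_nm``.

        Linear interpolation inside the support, zero outside.
        """
        grid = np.asarray(grid_nm, dtype=float)
        if grid.size == 0:
            raise ValueError("resampling grid is empty")
        if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
            raise ValueError("resampling grid must be 1-D and strictly increasing")
        return Spectrum(grid, self(grid))

    def scaled(self, factor: float) -> "Spectrum":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Spectrum(self.wavelengths_nm, self.values * factor)

    def shifted(self, delta_nm: float) -> "Spectrum":
        """Rigid shift of the whole curve along the wavelength axis."""
        return Spectrum(self.wavelengths_nm + delta_nm, self.values)

    # ---- two-column CSV I/O (wavelength_nm, value); '#' comments -------
    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        if data.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
        order = np.argsort(data[:, 0])
        return cls(data[order, 0], data[order, 1])

    def to_csv(self, path, comment: str | None = None) -> None:
        header = "wavelength_nm,value"
        if comment:
            header = comment + "\n" + header
        np.savetxt(path, np.column_stack([self.wavelengths_nm, self.values]),
                   delimiter=",", header=header, comments="# ", fmt="%.10g")


@dataclass(frozen=True)
class LaserLine:
    """Reference laser treated as an exact spectral line (delta function)."""

    wavelength_nm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.wavelength_nm) or self.wavelength_nm <= 0:
            raise ValueError("laser wavelength must be a positive finite number")


@dataclass(frozen=True)
class SpectralEfficiency:
    """Overlap-integral efficiency of a source against an absorber,
    relative to a laser line, plus the powermeter-responsivity correction.

    ``epsilon`` <= 1 whenever the absorption at the reference wavelength is
    the absorber's local maximum; ``detector_correction`` is ~1 for a flat
    detector.
    """

    epsilon: float
    detector_correction: float
    reference_nm: float
    weighting: str = field(default="energy")

    def __post_init__(self) -> None:
        if not 0 < self.epsilon:
            raise ValueError("epsilon must be positive")
        if self.detector_correction <= 0:
            raise ValueError("detector correction must be positive")


def fwhm_interval(spectrum: Spectrum, *, ripple_tol: float = 0.05,
                  smooth_window: int = 1) -> tuple[float, float]:
    """Full-width-half-maximum interval of a single-peaked spectrum.

    Returns the lowest and highest wavelengths at half the peak value,
    linearly interpolated between samples.  Secondary local maxima with
    prominence below ``ripple_tol`` of the peak are treated as measurement
    ripple and ignored; anything larger raises (multimodal).  A flat
    spectrum raises.  ``smooth_window`` > 1 applies a moving average before
    the peak search (the reported crossings still use the raw values).
    """
    v = spectrum.values
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        v = np.convolve(v, kernel, mode="same")
    peak = float(v.max())
    if peak <= 0 or np.ptp(v) < 1e-12 * peak:
        raise ValueError("fwhm undefined: spectrum is flat")
    peaks, props = find_peaks(v, prominence=ripple_tol * peak)
    # interior peak count; a monotone-edge maximum is not found by find_peaks
    if len(peaks) > 1:
        raise ValueError(
            f"fwhm undefined: spectrum is multimodal "
            f"({len(peaks)} peaks with prominence above {ripple_tol:.0%} of maximum)")

    wl = spectrum.wavelengths_nm
    raw = spectrum.values
    i_peak = int(np.argmax(raw))
    half = raw[i_peak] / 2.0

    def _cross(i_from: int, step: int) -> float:
        i = i_peak
        while 0 <= i + step < len(raw) and raw[i + step] >= half:
            i += step
        j = i + step
        if j < 0 or j >= len(raw):
            raise ValueError("fwhm undefined: half-maximum never reached within support")
        # linear interpolation between samples i (>= half) and j (< half)
        frac = (raw[i] - half) / (raw[i] - raw[j])
        return float(wl[i] + frac * (wl[j] - wl[i]))

    return _cross(i_peak, -1), _cross(i_peak, +1)


def _union_grid(*spectra: Spectrum, lo: float, hi: float) -> np.ndarray:
    grid = np.unique(np.concatenate([s.wavelengths_nm for s in spectra]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        raise ValueError("spectra supports are disjoint")
    return grid


def _integrate(grid: np.ndarray, integrand) -> float:
    """Per-interval Simpson rule on the union grid.

    Between consecutive knots every factor is linear, so the integrand is
    a polynomial of degree <= 3 (product of two spectra and an optional
    wavelength weight); Simpson with the interval midpoint integrates
    that exactly.
    """
    mid = 0.5 * (grid[:-1] + grid[1:])
    h = np.diff(grid)
    g0 = integrand(grid[:-1])
    gm = integrand(mid)
    g1 = integrand(grid[1:])
    return float(np.sum(h / 6.0 * (g0 + 4.0 * gm + g1)))


def spectral_efficiency(source: Spectrum, absorber: Spectrum,
                        reference: LaserLine,
                        detector: Spectrum | None = None,
                        *, weighting: str = "energy") -> SpectralEfficiency:
    """Spectral efficiency of ``source`` for exciting ``absorber``,
    relative to a laser line at ``reference``.

    epsilon            = [int S*A / int S] / A(ref)
    detector_correction = [int S*R / int S] / R(ref)

    Integrals run over the union grid of the inputs restricted to the
    source support (the source is zero outside it), with a per-interval
    Simpson rule that is exact for the piecewise-linear interpolation
    model, including the product of two spectra.  ``weighting='photon'``
    weights each integrand by wavelength, counting photons rather than
    energy; the default is energy-weighted.  ``detector=None`` means a
    spectrally flat powermeter (correction 1).
    """
    if weighting not in ("energy", "photon"):
        raise ValueError(f"unknown weighting {weighting!r}")
    lo, hi = source.support
    grid = _union_grid(source, absorber, *( [detector] if detector else [] ),
                       lo=lo, hi=hi)

    def w(x):
        return x if weighting == "photon" else 1.0

    norm = _integrate(grid, lambda x: source(x) * w(x))
    if norm <= 0:
        raise ValueError("source has zero integral on the common grid")

    a_ref = float(absorber(np.array([reference.wavelength_nm]))[0])
    if a_ref <= 0:
        raise ValueError(
            f"absorber is zero at the reference wavelength {reference.wavelength_nm} nm")
    overlap = _integrate(grid, lambda x: source(x) * absorber(x) * w(x))
    if overlap <= 0:
        raise ValueError("source and absorber supports are disjoint")
    eps = float(overlap / norm / a_ref)

    if detector is None:
        corr = 1.0
    else:
        r_ref = float(detector(np.array([reference.wavelength_nm]))[0])
        if r_ref <= 0:
            raise ValueError(
                f"detector responsivity is zero at {reference.wavelength_nm} nm")
        corr = float(_integrate(grid, lambda x: source(x) * detector(x) * w(x))
                     / norm / r_ref)

    return SpectralEfficiency(epsilon=eps, detector_correction=corr,
                              reference_nm=reference.wavelength_nm,
                              weighting=weighting)


def effective_dose(dose_Jcm2: float, eff: SpectralEfficiency) -> float:
    """Laser-equivalent light dose: fluence scaled by the spectral efficiency.

    The detector correction is *not* applied here — it belongs to the
    irradiance reading (see :func:`correct_reading`) and must be applied
    before fluence accumulation.
    """
    if dose_Jcm2 < 0:
        raise ValueError("dose must be non-negative")
    return dose_Jcm2 * eff.epsilon


def correct_reading(reading_mWcm2: float, eff: SpectralEfficiency) -> float:
    """True broadband irradiance from a powermeter reading calibrated at
    the reference line: reading / detector_correction."""
    if reading_mWcm2 < 0:
        raise ValueError("reading must be non-negative")
    return reading_mWcm2 / eff.detector_correction
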