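"""Viability normalisation and four-parameter logistic dose-response fits.

Raw plate-reader luminescence is anchored to the plate's own controls: the
NDNL group (no drug, no light) defines 100 % viability and the MO group
(media only, no cells) defines 0 %,

    v = 100 * (raw - mean(MO)) / (mean(NDNL) - mean(MO)).

The dose-response curve is the standard four-parameter logistic (4PL,
"inhibitor vs normalised response, variable slope"):

    v(d) = bottom + (top - bottom) / (1 + (d / EC50)^h)

fitted by nonlinear least squares with EC50 parameterised on a log10
scale.  By construction the fitted curve passes through (top + bottom)/2
at d = EC50.  Multiplying an LED-derived EC50 by the source's spectral
efficiency epsilon yields the *effective* EC50 on the laser-equivalent
dose scale (laser fits use epsilon = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .spectra import SpectralEfficiency

__all__ = [
    "ViabilityTable",
    "DoseResponseFit",
    "normalize_viability",
    "fit_4pl",
    "effective_ec50",
    "four_param_logistic",
]

_CONTROL_100 = "NDNL"
_CONTROL_0 = "MO"


@dataclass
class ViabilityTable:
    """Per-well raw luminescence with group labels, roles and doses.

    ``data`` columns: well, group, role, dose_Jcm2, luminescence.
    """

    data: pd.DataFrame

    REQUIRED = ("well", "group", "role", "dose_Jcm2", "luminescence")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"viability table missing columns: {missing}")
        for ctrl in (_CONTROL_100, _CONTROL_0):
            n = (self.data["role"] == ctrl).sum()
            if n < 2:
                raise ValueError(
                    f"control {ctrl} needs >= 2 replicates, found {n}")

    @classmethod
    def from_csv(cls, path) -> "ViabilityTable":
        return cls(pd.read_csv(path, comment="#"))

    def control_mean(self, role: str) -> float:
        return float(self.data.loc[self.data["role"] == role, "luminescence"].mean())


def normalize_viability(table: ViabilityTable) -> pd.DataFrame:
    """Anchor raw luminescence to the plate controls, returning the table
    with a ``viability_pct`` column added."""
    hi = table.control_mean(_CONTROL_100)
    lo = table.control_mean(_CONTROL_0)
    if hi <= lo:
        raise ValueError(
            f"NDNL control mean ({hi:g}) must exceed MO control mean ({lo:g})")
    out = table.data.copy()
    out["viability_pct"] = 100.0 * (out["luminescence"] - lo) / (hi - lo)
    return out


def four_param_logistic(dose, top, bottom, ec50, hill):
    """v(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill)."""
    d = np.maximum(np.asarray(dose, dtype=float), 1e-12)
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    ec50: float
    hill: float
    se: dict          # per-parameter standard errors
    constrained: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.bottom >= self.top:
            raise ValueError("fit requires bottom < top")

    def predict(self, dose):
        return four_param_logistic(dose, self.top, self.bottom, self.ec50, self.hill)


def _initial_guess(doses: np.ndarray, viab: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(doses)
    d_sorted = doses[order]
    v_sorted = viab[order]
    uniq = np.unique(d_sorted)
    means = np.array([v_sorted[d_sorted == u].mean() for u in uniq])
    top = float(means[0])
    bottom = float(means[-1])
    mid = (top + bottom) / 2.0
    # first crossing of the midpoint on the dose-mean curve, interpolated in log dose
    ec50 = float(np.sqrt(uniq[0] * uniq[-1]))
    for i in range(len(uniq) - 1):
        a, b = means[i], means[i + 1]
        if (a - mid) * (b - mid) <= 0 and a != b:
            f = (a - mid) / (a - b)
            ec50 = float(10 ** (np.log10(uniq[i])
                                + f * (np.log10(uniq[i + 1]) - np.log10(uniq[i]))))
            break
    return top, bottom, max(ec50, 1e-9), 1.0


def fit_4pl(doses, viabilities, *, constrain: bool = False,
            flat_tol: float = 1e-6) -> DoseResponseFit:
    """Least-squares 4PL fit of viability (%) against dose (J/cm^2).

    EC50 is fitted on a log10 scale (positivity for free).  ``constrain``
    pins top = 100 and bottom = 0.  A response with no dose effect —
    per-dose means spanning less than ``flat_tol`` of the data range —
    raises rather than returning a meaningless EC50.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viabilities must have the same shape")
    pos = d > 0
    uniq = np.unique(d[pos])
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct nonzero doses")
    means = np.array([v[d == u].mean() for u in uniq])
    span = np.ptp(means)
    scale = max(np.ptp(v), 1.0)
    if span <= flat_tol * scale:
        raise ValueError("no dose effect: response is flat across doses")

    top0, bottom0, ec500, h0 = _initial_guess(d[pos], v[pos])

    if constrain:
        def model(dd, log_ec50, hill):
            return four_param_logistic(dd, 100.0, 0.0, 10.0 ** log_ec50, hill)
        p0 = [np.log10(ec500), h0]
        names = ["log10_ec50", "hill"]
    else:
        def model(dd, top, bottom, log_ec50, hill):
            return four_param_logistic(dd, top, bottom, 10.0 ** log_ec50, hill)
        if abs(top0 - bottom0) < 1e-6:
            top0, bottom0 = top0 + 1.0, bottom0 - 1.0
        p0 = [top0, bottom0, np.log10(ec500), h0]
        names = ["top", "bottom", "log10_ec50", "hill"]

    try:
        with warnings.catch_warnings():
            # a noise-free fit has singular covariance; SEs are NaN-flagged
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(model, d, v, p0=p0, maxfev=20000,
                                   xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
    if constrain:
        log_ec50, hill = popt
        top, bottom = 100.0, 0.0
    else:
        top, bottom, log_ec50, hill = popt

    with np.errstate(invalid="ignore"):
        se_vals = np.sqrt(np.diag(pcov))
    se = dict(zip(names, (float(s) for s in se_vals)))
    se["ec50"] = float(np.log(10.0) * (10.0 ** log_ec50) * se.get("log10_ec50", np.nan))

    if hill < 0:
        # (d/ec50)^h with negative h mirrors the curve: renormalise to the
        # canonical orientation so top is always the low-dose asymptote
        top, bottom, hill = bottom, top, -hill
        se["top"], se["bottom"] = se.get("bottom", np.nan), se.get("top", np.nan)
    if top <= bottom:
        raise RuntimeError("4PL fit degenerate: fitted top <= bottom")
    return DoseResponseFit(top=float(top), bottom=float(bottom),
                           ec50=float(10.0 ** log_ec50), hill=float(hill),
                           se=se, constrained=constrain)


def effective_ec50(fit: DoseResponseFit,
                   eff: SpectralEfficiency | float = 1.0) -> float:
    """EC50 on the laser-equivalent dose scale: EC50 * epsilon.

    Laser-derived fits pass epsilon = 1 (their dose scale is already the
    reference)."""
    eps = eff.epsilon if isinstance(eff, SpectralEfficiency) else float(eff)
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    return fit.ec50 * eps
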