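"""Radiometric model of the LED array at the sample plane.

The source is a 5x5 grid of high-power 690 nm LEDs spanning 33 mm
edge-to-edge (pitch 33/4 mm), each emitting 520 mW into a lens-narrowed
radially symmetric beam.  Each emitter is modelled with a Gaussian angular
intensity profile I(theta) = I0 * exp(-ln2 * theta^2 / theta_h^2), where
theta_h is the half-intensity half-angle (default 12 deg, i.e. a 24 deg
full cone), normalised so the profile integrates to the emitter's optical
power over the hemisphere.  Irradiance at a sample-plane point is the
superposition of per-emitter contributions with inverse-square falloff and
cosine obliquity.

The Fresnel lens + diffuser stack is not ray-traced: its collimating
effect is absorbed into the effective angular profile and an overall
transmission factor that can be calibrated so the peak field matches the
measured 400 mW/cm^2 at full duty.

The uniformity figure of merit for a 3x3-well exposure is the relative
power difference between the centre well and the least-illuminated corner
well, 100 * (centre - min(corners)) / centre — smaller is flatter.  A
circular-Gaussian beam stands in for the laser comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from shapely import contains_xy
from shapely.geometry import Polygon

from .plate import PlateFormat

__all__ = [
    "EmitterArray",
    "IrradianceField",
    "ApertureMask",
    "simulate_field",
    "gaussian_laser_field",
    "per_well_irradiance",
    "uniformity_metric",
]


@dataclass(frozen=True)
class EmitterArray:
    """Planar grid of identical radially symmetric emitters."""

    positions_mm: np.ndarray          # (n, 2) emitter centres
    power_mW: float = 520.0           # optical power per emitter
    half_angle_deg: float = 12.0      # half-intensity half-angle
    transmission: float = 1.0         # lens/diffuser throughput scale

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if pos.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if self.power_mW <= 0 or not 0 < self.half_angle_deg < 90:
            raise ValueError("power and half-angle must be positive (half-angle < 90 deg)")
        if not 0 < self.transmission <= 1:
            raise ValueError("transmission must be in (0, 1]")
        object.__setattr__(self, "positions_mm", pos)

    @classmethod
    def led_5x5(cls, extent_mm: float = 33.0, **kw) -> "EmitterArray":
        """The default 5x5 array spanning ``extent_mm`` edge-to-edge,
        centred on the origin."""
        c = np.linspace(-extent_mm / 2, extent_mm / 2, 5)
        xx, yy = np.meshgrid(c, c)
        return cls(positions_mm=np.column_stack([xx.ravel(), yy.ravel()]), **kw)

    def calibrated(self, z_mm: float, peak_mWcm2: float = 400.0,
                   grid_halfspan_mm: float = 30.0, n: int = 121) -> "EmitterArray":
        """Rescale the transmission so the peak sample-plane irradiance at
        height ``z_mm`` equals ``peak_mWcm2`` (full duty)."""
        axis = np.linspace(-grid_halfspan_mm, grid_halfspan_mm, n)
        f = simulate_field(self, z_mm, axis, axis)
        scale = peak_mWcm2 / f.values.max()
        return EmitterArray(self.positions_mm, self.power_mW,
                            self.half_angle_deg,
                            min(self.transmission * scale, 1.0))


def _radiant_intensity_norm(half_angle_rad: float) -> float:
    """Hemisphere integral of exp(-ln2 theta^2/theta_h^2) over solid angle,
    used to scale the profile to unit power."""
    ln2 = np.log(2.0)
    val, _ = quad(lambda t: np.exp(-ln2 * t * t / half_angle_rad**2) * np.sin(t),
                  0.0, np.pi / 2, limit=200)
    return 2.0 * np.pi * val


@dataclass
class IrradianceField:
    """2-D irradiance map (mW/cm^2) on the sample plane."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    values: np.ndarray  # shape (len(y), len(x))
    z_mm: float

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.y_mm), len(self.x_mm)):
            raise ValueError("field shape does not match its axes")
        if np.any(self.values < 0):
            raise ValueError("irradiance must be non-negative")

    def plane_power_mW(self) -> float:
        """Irradiance integrated over the sampled plane (mW)."""
        # values are mW/cm^2; axes are mm -> area factor 1/100
        return float(np.trapezoid(np.trapezoid(self.values, self.x_mm, axis=1),
                                  self.y_mm)) / 100.0

    def masked(self, mask: "ApertureMask") -> "IrradianceField":
        xx, yy = np.meshgrid(self.x_mm, self.y_mm)
        keep = mask.contains(xx.ravel(), yy.ravel()).reshape(xx.shape)
        return IrradianceField(self.x_mm, self.y_mm,
                               np.where(keep, self.values, 0.0), self.z_mm)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g",
                   header=f"irradiance mW/cm^2; z_mm={self.z_mm}; "
                          f"x {self.x_mm[0]}..{self.x_mm[-1]} mm ({len(self.x_mm)}); "
                          f"y {self.y_mm[0]}..{self.y_mm[-1]} mm ({len(self.y_mm)})",
                   comments="# ")


@dataclass
class ApertureMask:
    """Open region(s) of the spatial light filter, as polygons in plate
    coordinates.  An empty polygon list is a fully closed mask."""

    polygons: list[Polygon] = field(default_factory=list)

    @classmethod
    def rectangle(cls, cx_mm: float, cy_mm: float,
                  width_mm: float, height_mm: float) -> "ApertureMask":
        w, h = width_mm / 2, height_mm / 2
        return cls([Polygon([(cx_mm - w, cy_mm - h), (cx_mm + w, cy_mm - h),
                             (cx_mm + w, cy_mm + h), (cx_mm - w, cy_mm + h)])])

    @classmethod
    def well_block(cls, fmt: PlateFormat, wells: list[str],
                   margin_mm: float = 1.0) -> "ApertureMask":
        """Rectangular opening covering a block of wells (the Fig-style
        3x3 / 2x3 / 2x2 footprints), with a clearance margin."""
        xy = np.array([fmt.well_position_mm(w) for w in wells])
        r = fmt.well_diameter_mm / 2 + margin_mm
        lo = xy.min(axis=0) - r
        hi = xy.max(axis=0) + r
        return cls([Polygon([(lo[0], lo[1]), (hi[0], lo[1]),
                             (hi[0], hi[1]), (lo[0], hi[1])])])

    @classmethod
    def closed(cls) -> "ApertureMask":
        return cls([])

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(x.shape, dtype=bool)
        for poly in self.polygons:
            out |= contains_xy(poly, x, y)
        return out


def simulate_field(array: EmitterArray, z_mm: float,
                   x_mm, y_mm) -> IrradianceField:
    """Superpose per-emitter irradiance on the plane at height ``z_mm``.

    Per emitter, E(point) = P * T * f(theta) * cos(theta) / r^2 with f the
    power-normalised Gaussian angular profile, r the emitter-to-point
    distance and theta the off-axis angle.
    """
    if z_mm <= 0:
        raise ValueError("sample plane height must be positive")
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("field grid is empty")
    half_rad = np.deg2rad(array.half_angle_deg)
    norm = _radiant_intensity_norm(half_rad)
    i0 = array.power_mW * array.transmission / norm  # mW/sr at theta=0

    xx, yy = np.meshgrid(x, y)
    total = np.zeros_like(xx)
    ln2 = np.log(2.0)
    for ex, ey in array.positions_mm:
        dx = xx - ex
        dy = yy - ey
        r2_mm2 = dx * dx + dy * dy + z_mm * z_mm
        r_mm = np.sqrt(r2_mm2)
        cos_t = z_mm / r_mm
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        intensity = i0 * np.exp(-ln2 * theta * theta / half_rad**2)  # mW/sr
        total += intensity * cos_t / (r2_mm2 / 100.0)  # mm^2 -> cm^2
    return IrradianceField(x, y, total, z_mm)


def gaussian_laser_field(x_mm, y_mm, z_mm: float, *,
                         centre_mm: tuple[float, float] = (0.0, 0.0),
                         waist_mm: float = 50.0,
                         peak_mWcm2: float = 100.0) -> IrradianceField:
    """Circular-Gaussian beam comparator: E = peak * exp(-2 r^2 / w^2)."""
    if waist_mm <= 0 or peak_mWcm2 <= 0:
        raise ValueError("waist and peak must be positive")
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    xx, yy = np.meshgrid(x, y)
    r2 = (xx - centre_mm[0]) ** 2 + (yy - centre_mm[1]) ** 2
    return IrradianceField(x, y, peak_mWcm2 * np.exp(-2.0 * r2 / waist_mm**2), z_mm)


def per_well_irradiance(fld: IrradianceField, fmt: PlateFormat,
                        wells: list[str],
                        mask: ApertureMask | None = None) -> dict[str, float]:
    """Mean irradiance over each well's disc footprint (mW/cm^2).

    Grid points under a closed part of the mask contribute zero; a well
    fully outside the open region therefore reads 0.
    """
    f = fld.masked(mask) if mask is not None else fld
    xx, yy = np.meshgrid(f.x_mm, f.y_mm)
    out: dict[str, float] = {}
    r = fmt.well_diameter_mm / 2.0
    for w in wells:
        cx, cy = fmt.well_position_mm(w)
        if not (f.x_mm[0] <= cx <= f.x_mm[-1] and f.y_mm[0] <= cy <= f.y_mm[-1]):
            raise ValueError(f"well {w} at ({cx:g}, {cy:g}) mm lies outside the field grid")
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        if not inside.any():
            raise ValueError(f"field grid too coarse to sample well {w}")
        out[w] = float(f.values[inside].mean())
    return out


def uniformity_metric(per_well: dict[str, float] | np.ndarray) -> float:
    """Centre-to-worst-corner relative power difference of a 3x3 block,
    in percent: 100 * (centre - min(corners)) / centre."""
    if isinstance(per_well, dict):
        vals = np.array(list(per_well.values()), dtype=float)
    else:
        vals = np.asarray(per_well, dtype=float).ravel()
    if vals.size != 9:
        raise ValueError("uniformity metric needs exactly the 9 values of a 3x3 block")
    grid = vals.reshape(3, 3)
    centre = grid[1, 1]
    if centre <= 0:
        raise ValueError("centre well irradiance must be positive")
    corners = grid[[0, 0, 2, 2], [0, 2, 0, 2]]
    return float(100.0 * (centre - corners.min()) / centre)
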