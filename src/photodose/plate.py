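"""Well-plate geometry, experimental-group layouts and treatment planning.

A dose-response PDT plate carries replicate groups of wells: treatment
groups at graded light doses plus the four standard controls — DNL (drug,
no light), LND (light, no drug), NDNL (no drug, no light; defines 100 %
viability) and MO (media only; defines 0 %).  Two treatment series are
*staggered* across the plate so that a plate placed one group-pitch off
its intended alignment produces an obviously wrong dose pattern instead of
a silently shifted one.

Planning converts a layout into an ordered visit list: for each group with
a nonzero dose, the plate position that centres the group over the open
aperture, the stepper-motor steps to reach it, the PWM duty realising the
requested irradiance, and the exposure time delivering the dose at the
*achieved* (quantised) irradiance.  The LND control is appended with the
maximum treatment dose, mirroring standard PDT plate practice.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .pwm import IrradianceCalibration, PwmConfig, duty_for_irradiance, exposure_time

__all__ = [
    "Role",
    "PlateFormat",
    "Group",
    "PlateLayout",
    "MotionConfig",
    "Visit",
    "TreatmentPlan",
    "well_to_rc",
    "rc_to_well",
    "validate_layout",
    "motion_steps",
    "plan_experiment",
    "canonical_96well_layout",
]

_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


def well_to_rc(name: str) -> tuple[int, int]:
    """'A1' -> (0, 0).  Row letter, 1-based column number."""
    m = _WELL_RE.match(name.strip())
    if not m:
        raise ValueError(f"malformed well name {name!r}")
    return ord(m.group(1).upper()) - ord("A"), int(m.group(2)) - 1


def rc_to_well(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1}"


class Role(str, Enum):
    TREATMENT = "treatment"
    DNL = "DNL"    # drug, no light
    LND = "LND"    # light, no drug
    NDNL = "NDNL"  # no drug, no light (100 % viability anchor)
    MO = "MO"      # media only (0 % viability anchor)


@dataclass(frozen=True)
class PlateFormat:
    """Microplate geometry.  Defaults follow the ANSI/SLAS 96-well
    standard: 9.0 mm well pitch, A1 centre 14.38/11.24 mm from the plate
    corner."""

    n_rows: int = 8
    n_cols: int = 12
    well_pitch_mm: float = 9.0
    a1_offset_mm: tuple[float, float] = (14.38, 11.24)
    well_diameter_mm: float = 6.5

    def __post_init__(self) -> None:
        if self.well_pitch_mm <= 0 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("invalid plate geometry")

    @classmethod
    def plate96(cls) -> "PlateFormat":
        return cls()

    @classmethod
    def plate24(cls) -> "PlateFormat":
        return cls(n_rows=4, n_cols=6, well_pitch_mm=19.3,
                   a1_offset_mm=(13.49, 15.13), well_diameter_mm=15.6)

    def well_position_mm(self, well: str) -> tuple[float, float]:
        """(x, y) of a well centre; x along columns, y along rows."""
        r, c = well_to_rc(well)
        if r >= self.n_rows or c >= self.n_cols:
            raise ValueError(f"well {well} outside a "
                             f"{self.n_rows}x{self.n_cols} plate")
        x0, y0 = self.a1_offset_mm
        return x0 + c * self.well_pitch_mm, y0 + r * self.well_pitch_mm


@dataclass
class Group:
    label: str
    role: Role
    wells: list[str]
    dose_Jcm2: float = 0.0

    def rcs(self) -> list[tuple[int, int]]:
        return [well_to_rc(w) for w in self.wells]


@dataclass
class PlateLayout:
    format: PlateFormat
    groups: list[Group]
    staggered: bool = True

    def group(self, label: str) -> Group:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    # ---- JSON I/O ------------------------------------------------------
    @classmethod
    def from_json(cls, path) -> "PlateLayout":
        with open(path) as fh:
            obj = json.load(fh)
        fmt_name = obj.get("format", "96")
        fmt = PlateFormat.plate24() if str(fmt_name).startswith("24") else PlateFormat.plate96()
        groups = [Group(label=g["label"], role=Role(g["role"]),
                        wells=list(g["wells"]),
                        dose_Jcm2=float(g.get("dose_Jcm2", 0.0)))
                  for g in obj["groups"]]
        return cls(format=fmt, groups=groups,
                   staggered=bool(obj.get("staggered", True)))

    def to_json(self, path) -> None:
        obj = {
            "format": f"{self.format.n_rows * self.format.n_cols}",
            "staggered": self.staggered,
            "groups": [{"label": g.label, "role": g.role.value,
                        "wells": g.wells, "dose_Jcm2": g.dose_Jcm2}
                       for g in self.groups],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def validate_layout(layout: PlateLayout) -> list[str]:
    """Return the list of layout violations (empty list = valid).

    Checks well-name validity and bounds, disjointness, equal replicate
    counts, presence of all four control roles, and — in staggered mode —
    that no two treatment groups carrying the same dose sit in adjacent
    illumination footprints (the misalignment tell-tale).
    """
    violations: list[str] = []
    seen: dict[tuple[int, int], str] = {}
    for g in layout.groups:
        for w in g.wells:
            rc = well_to_rc(w)  # raises on malformed names
            if rc[0] >= layout.format.n_rows or rc[1] >= layout.format.n_cols:
                violations.append(f"well {w} of group {g.label} outside plate")
            if rc in seen:
                violations.append(
                    f"well assigned twice: {w} in {seen[rc]} and {g.label}")
            seen[rc] = g.label

    counts = {g.label: len(g.wells) for g in layout.groups}
    if len(set(counts.values())) > 1:
        violations.append(f"unequal replicate counts: {counts}")

    roles = {g.role for g in layout.groups}
    for need in (Role.DNL, Role.LND, Role.NDNL, Role.MO):
        if need not in roles:
            violations.append(f"missing control: {need.value}")

    if layout.staggered:
        treatments = [g for g in layout.groups if g.role is Role.TREATMENT]
        for i, a in enumerate(treatments):
            for b in treatments[i + 1:]:
                if a.dose_Jcm2 != b.dose_Jcm2:
                    continue
                if _footprints_adjacent(a.rcs(), b.rcs()):
                    violations.append(
                        f"staggering violated: groups {a.label} and {b.label} "
                        f"share dose {a.dose_Jcm2:g} J/cm^2 in adjacent footprints")
    return violations


def _footprints_adjacent(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    """True when any wells of the two groups touch (Chebyshev distance <= 1)."""
    for ra, ca in a:
        for rb, cb in b:
            if max(abs(ra - rb), abs(ca - cb)) <= 1:
                return True
    return False


@dataclass(frozen=True)
class MotionConfig:
    """Two independent linear screw axes driven by stepper motors.

    The printed step size of the deployed actuators is 25 um/step; note a
    5 mm screw pitch at 400 steps/rotation works out to 12.5 um, so the
    value is configuration, not physics.
    """

    step_size_um: float = 25.0
    steps_per_s: float = 800.0
    travel_mm: tuple[float, float] = (150.0, 150.0)

    def __post_init__(self) -> None:
        if self.step_size_um <= 0 or self.steps_per_s <= 0:
            raise ValueError("step size and rate must be positive")


@dataclass(frozen=True)
class AxisMove:
    steps: int
    direction: int       # +1, -1, or 0
    residual_mm: float   # requested minus realised displacement


def motion_steps(from_mm: tuple[float, float], to_mm: tuple[float, float],
                 cfg: MotionConfig) -> tuple[AxisMove, AxisMove]:
    """Per-axis step counts for a move, with the sub-step residual error."""
    moves = []
    for f, t in zip(from_mm, to_mm):
        if not (np.isfinite(f) and np.isfinite(t)):
            raise ValueError("coordinates must be finite")
        delta = t - f
        step_mm = cfg.step_size_um / 1000.0
        steps = int(round(delta / step_mm))
        moves.append(AxisMove(steps=abs(steps),
                              direction=int(np.sign(steps)),
                              residual_mm=delta - steps * step_mm))
    return moves[0], moves[1]


@dataclass
class Visit:
    group: str
    target_mm: tuple[float, float]
    steps: tuple[AxisMove, AxisMove]
    duty: float
    irradiance_mWcm2: float      # achieved (quantised) irradiance
    requested_mWcm2: float
    exposure_s: float
    dose_Jcm2: float
    wells: list[str]


@dataclass
class TreatmentPlan:
    visits: list[Visit]
    layout: PlateLayout
    total_illumination_s: float
    move_count: int
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        rows = [{
            "visit": i, "group": v.group,
            "x_mm": v.target_mm[0], "y_mm": v.target_mm[1],
            "steps_x": v.steps[0].steps * v.steps[0].direction,
            "steps_y": v.steps[1].steps * v.steps[1].direction,
            "duty": v.duty, "irradiance_mWcm2": v.irradiance_mWcm2,
            "seconds": v.exposure_s,
        } for i, v in enumerate(self.visits)]
        pd.DataFrame(rows).to_csv(path, index=False)


def plan_experiment(layout: PlateLayout, irradiance_mWcm2: float,
                    calib: IrradianceCalibration,
                    pwm_cfg: PwmConfig | None = None,
                    motion_cfg: MotionConfig | None = None,
                    *, home_mm: tuple[float, float] = (0.0, 0.0),
                    order: str = "row-major") -> TreatmentPlan:
    """Build the full automated treatment plan for a validated layout.

    Visits cover every treatment group with a nonzero dose exactly once,
    row-major by the group's top-left well by default, then the LND
    control at the maximum treatment dose.  Exposure times use the
    achieved irradiance, so each visit's delivered fluence equals its
    requested dose exactly; the quantisation shows up as the difference
    between requested and achieved irradiance, reported per visit.
    """
    pwm_cfg = pwm_cfg or PwmConfig()
    motion_cfg = motion_cfg or MotionConfig()
    violations = validate_layout(layout)
    if violations:
        raise ValueError("invalid layout: " + "; ".join(violations))

    treatments = [g for g in layout.groups
                  if g.role is Role.TREATMENT and g.dose_Jcm2 > 0]
    if order == "row-major":
        treatments.sort(key=lambda g: min(g.rcs()))
    elif order != "as-given":
        raise ValueError(f"unknown visit order {order!r}")

    queue: list[tuple[Group, float]] = [(g, g.dose_Jcm2) for g in treatments]
    if treatments:
        max_dose = max(g.dose_Jcm2 for g in treatments)
        lnd = next(g for g in layout.groups if g.role is Role.LND)
        queue.append((lnd, max_dose))

    visits: list[Visit] = []
    pos = home_mm
    total_light = 0.0
    for g, dose in queue:
        centre = _group_centre_mm(layout.format, g)
        try:
            duty, achieved = duty_for_irradiance(irradiance_mWcm2, calib, pwm_cfg)
        except ValueError as exc:
            raise ValueError(f"group {g.label}: {exc}") from exc
        t = exposure_time(dose, achieved)
        visits.append(Visit(group=g.label, target_mm=centre,
                            steps=motion_steps(pos, centre, motion_cfg),
                            duty=duty, irradiance_mWcm2=achieved,
                            requested_mWcm2=irradiance_mWcm2,
                            exposure_s=t, dose_Jcm2=dose, wells=list(g.wells)))
        total_light += t
        pos = centre

    meta = {
        "requested_irradiance_mWcm2": irradiance_mWcm2,
        "irradiance_quantisation_note": (
            "exposure times use the achieved (duty-quantised) irradiance; "
            "exposures are not re-quantised to whole PWM periods — the "
            "residual sub-period dose error per visit is bounded by "
            "irradiance * one carrier period"),
        "sub_period_dose_bound_Jcm2": (
            max((v.irradiance_mWcm2 for v in visits), default=0.0)
            / 1000.0 / pwm_cfg.carrier_hz),
    }
    return TreatmentPlan(visits=visits, layout=layout,
                         total_illumination_s=total_light,
                         move_count=len(visits), metadata=meta)


def _group_centre_mm(fmt: PlateFormat, g: Group) -> tuple[float, float]:
    xy = np.array([fmt.well_position_mm(w) for w in g.wells])
    return float(xy[:, 0].mean()), float(xy[:, 1].mean())


def canonical_96well_layout(doses_Jcm2: tuple[float, ...] = (2, 4, 6, 8, 10, 12),
                            replicates: int = 6) -> PlateLayout:
    """The standard dose-response layout: 16 groups x 6 replicates filling
    a 96-well plate — two staggered treatment series over six doses plus
    the four controls, each group a 2x3 well block.

    The two series carry identical dose ladders but are arranged so that
    equal-dose groups never occupy adjacent blocks, which makes a plate
    misalignment show up as a scrambled dose-response curve.
    """
    if len(doses_Jcm2) != 6 or replicates != 6:
        raise ValueError("the canonical layout is 2 series x 6 doses x 6 replicates")
    d = list(doses_Jcm2)
    # 4x4 grid of 2-row x 3-col blocks; None entries are controls
    block_labels = [
        [("PDT1", d[0]), ("PDT1", d[1]), ("PDT1", d[2]), ("PDT1", d[3])],
        [("PDT2", d[2]), ("PDT2", d[3]), ("PDT2", d[0]), ("PDT2", d[1])],
        [("PDT1", d[4]), ("PDT1", d[5]), ("DNL", None), ("LND", None)],
        [("NDNL", None), ("MO", None), ("PDT2", d[4]), ("PDT2", d[5])],
    ]
    groups: list[Group] = []
    for br, row in enumerate(block_labels):
        for bc, (series, dose) in enumerate(row):
            wells = [rc_to_well(2 * br + r, 3 * bc + c)
                     for r in range(2) for c in range(3)]
            if dose is None:
                groups.append(Group(label=series, role=Role(series), wells=wells))
            else:
                groups.append(Group(label=f"{series}-{dose:g}J",
                                    role=Role.TREATMENT, wells=wells,
                                    dose_Jcm2=float(dose)))
    return PlateLayout(format=PlateFormat.plate96(), groups=groups, staggered=True)
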