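"""Virtual-hardware execution of a treatment plan.

A :class:`VirtualRig` stands in for the physical instrument — DAQ PWM
channel, two stepper axes, the LED array, and the on-board thermistor and
phototransistor — on a virtual clock, so a full plate experiment simulates
in milliseconds.  Executing a plan produces an :class:`EventLog`: a
totally ordered list of timestamped events (moves, illuminations, sensor
samples) plus per-well accumulated fluence.

Accounting is exact: a well inside the open aperture of a visit receives
achieved irradiance x on-time; wells never see light during motion.  A
thermal interlock projects the sample temperature along the plan with the
first-order thermal model and refuses plans that would cross the
configured threshold unless explicitly overridden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuits import DividerCircuit, NtcModel, divider_output
from .plate import MotionConfig, TreatmentPlan, motion_steps
from .pwm import PwmConfig
from .thermal import ThermalParams, steady_state

__all__ = ["VirtualRig", "EventLog", "InterlockError", "run_plan"]


class InterlockError(RuntimeError):
    """Raised when a plan's projected sample temperature crosses the
    safety threshold and no override is given."""


@dataclass
class EventLog:
    events: list[dict] = field(default_factory=list)
    fluence_Jcm2: dict[str, float] = field(default_factory=dict)
    completed: bool = True

    def add(self, t_s: float, kind: str, **data) -> None:
        if self.events:
            last = self.events[-1]["t_s"]
            if t_s < last - 1e-6:
                raise ValueError("events must be appended in time order")
            t_s = max(t_s, last)  # absorb float rounding of accumulated times
        self.events.append({"t_s": round(t_s, 9), "event": kind, **data})

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["event"] == kind]

    def total_fluence(self) -> float:
        return sum(self.fluence_Jcm2.values())

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")

    def fluence_summary(self, epsilon: float = 1.0) -> pd.DataFrame:
        rows = [{"well": w, "fluence_Jcm2": f,
                 "effective_Jcm2": f * epsilon}
                for w, f in sorted(self.fluence_Jcm2.items())]
        return pd.DataFrame(rows)


@dataclass
class VirtualRig:
    """Simulated instrument state.

    Deterministic for a given seed; the clock is virtual seconds.  Sensor
    readings are the model values plus seeded Gaussian noise (thermistor
    0.1 degC, photosensor 1 mW/cm^2-equivalent by default).
    """

    pwm_cfg: PwmConfig = field(default_factory=PwmConfig)
    motion_cfg: MotionConfig = field(default_factory=MotionConfig)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    thermistor_divider: DividerCircuit = field(
        default_factory=lambda: DividerCircuit(fixed_ohm=5000.0))
    ntc: NtcModel = field(default_factory=NtcModel)
    seed: int = 0
    sensor_rate_hz: float = 1.0
    temp_noise_C: float = 0.1
    photo_noise_mWcm2: float = 1.0
    interlock_threshold_C: float = 37.0
    settle_s: float = 0.0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self.position_mm: tuple[float, float] = (0.0, 0.0)
        self.position_steps: tuple[int, int] = (0, 0)
        self.clock_s: float = 0.0
        self.temp_C: float = self.thermal.t_env_C

    # first-order relaxation of the sample temperature toward a target
    def _relax(self, dt_s: float, target_C: float) -> None:
        self.temp_C = target_C - (target_C - self.temp_C) * np.exp(
            -dt_s / self.thermal.tau_s)


def _project_peak_temp(plan: TreatmentPlan, rig: VirtualRig) -> float:
    """Noise-free projection of the maximum sample temperature over the
    plan, including cool-down during moves."""
    temp = rig.thermal.t_env_C
    peak = temp
    pos = rig.position_mm
    for v in plan.visits:
        mx, my = motion_steps(pos, v.target_mm, rig.motion_cfg)
        dt_move = max(mx.steps, my.steps) / rig.motion_cfg.steps_per_s
        temp = rig.thermal.t_env_C - (rig.thermal.t_env_C - temp) * np.exp(
            -(dt_move + rig.settle_s) / rig.thermal.tau_s)
        t_inf = steady_state(v.irradiance_mWcm2, rig.thermal)
        temp = t_inf - (t_inf - temp) * np.exp(-v.exposure_s / rig.thermal.tau_s)
        peak = max(peak, temp)
        pos = v.target_mm
    return float(peak)


def run_plan(plan: TreatmentPlan, rig: VirtualRig, *,
             override_interlock: bool = False) -> EventLog:
    """Execute a treatment plan on the virtual rig.

    Visits run in order: move (both axes stepping simultaneously at the
    configured step rate), optional settling dwell, then illumination at
    the visit's duty for its exposure time, during which every well of
    the visit's open-aperture group accrues fluence and the sensors are
    sampled at the configured rate.  A target outside the travel range
    aborts with a partial log.
    """
    log = EventLog()
    peak = _project_peak_temp(plan, rig)
    if peak >= rig.interlock_threshold_C and not override_interlock:
        raise InterlockError(
            f"projected sample temperature {peak:.1f} degC crosses the "
            f"{rig.interlock_threshold_C:.1f} degC interlock; pass "
            f"override_interlock=True to run anyway")

    for w in {w for v in plan.visits for w in v.wells}:
        log.fluence_Jcm2.setdefault(w, 0.0)

    for v in plan.visits:
        tx, ty = v.target_mm
        lim_x, lim_y = rig.motion_cfg.travel_mm
        if not (0.0 <= tx <= lim_x and 0.0 <= ty <= lim_y):
            log.add(rig.clock_s, "abort", reason="motion out of travel range",
                    group=v.group, target_mm=[tx, ty])
            log.completed = False
            return log

        mx, my = motion_steps(rig.position_mm, v.target_mm, rig.motion_cfg)
        dt_move = max(mx.steps, my.steps) / rig.motion_cfg.steps_per_s
        log.add(rig.clock_s, "move_start", group=v.group,
                steps_x=mx.steps * mx.direction, steps_y=my.steps * my.direction)
        rig._relax(dt_move, rig.thermal.t_env_C)
        rig.clock_s += dt_move
        sx, sy = rig.position_steps
        rig.position_steps = (sx + mx.steps * mx.direction,
                              sy + my.steps * my.direction)
        rig.position_mm = v.target_mm
        log.add(rig.clock_s, "move_end", group=v.group,
                position_steps=list(rig.position_steps))
        if rig.settle_s > 0:
            rig._relax(rig.settle_s, rig.thermal.t_env_C)
            rig.clock_s += rig.settle_s

        log.add(rig.clock_s, "illuminate_start", group=v.group, duty=v.duty,
                irradiance_mWcm2=v.irradiance_mWcm2, planned_s=v.exposure_s)
        t_inf = steady_state(v.irradiance_mWcm2, rig.thermal)
        t_done = rig.clock_s + v.exposure_s
        if rig.sensor_rate_hz > 0:
            n_samples = int(v.exposure_s * rig.sensor_rate_hz)
            for k in range(1, n_samples + 1):
                dt = k / rig.sensor_rate_hz
                temp = t_inf - (t_inf - rig.temp_C) * np.exp(
                    -dt / rig.thermal.tau_s)
                t_read = temp + rig.temp_noise_C * rig._rng.standard_normal()
                v_read = divider_output(rig.thermistor_divider,
                                        rig.ntc.resistance(t_read))
                p_read = (v.irradiance_mWcm2
                          + rig.photo_noise_mWcm2 * rig._rng.standard_normal())
                log.add(rig.clock_s + dt, "sensor_sample",
                        temp_C=round(float(t_read), 4),
                        thermistor_V=round(float(v_read), 6),
                        photo_mWcm2=round(float(p_read), 4))
        rig._relax(v.exposure_s, t_inf)
        rig.clock_s = t_done
        for w in v.wells:
            log.fluence_Jcm2[w] += v.irradiance_mWcm2 * v.exposure_s / 1000.0
        log.add(rig.clock_s, "illuminate_end", group=v.group,
                delivered_Jcm2=v.irradiance_mWcm2 * v.exposure_s / 1000.0)
    return log
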