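import numpy as np
import pytest

import photodose as pv
from photodose.plate import (Group, MotionConfig, PlateFormat, PlateLayout,
                             Role, motion_steps, rc_to_well, well_to_rc)


class TestWellNames:
    @pytest.mark.parametrize("name,rc", [("A1", (0, 0)), ("H12", (7, 11)),
                                         ("C7", (2, 6))])
    def test_round_trip(self, name, rc):
        assert well_to_rc(name) == rc
        assert rc_to_well(*rc) == name

    @pytest.mark.parametrize("bad", ["1A", "A0x", "AA1", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError, match="malformed"):
            well_to_rc(bad)

    def test_out_of_bounds_position(self):
        with pytest.raises(ValueError, match="outside"):
            PlateFormat.plate96().well_position_mm("J1")


class TestLayoutValidation:
    def test_canonical_layout_is_valid(self, canonical_layout):
        assert pv.validate_layout(canonical_layout) == []
        assert len(canonical_layout.groups) == 16
        wells = [w for g in canonical_layout.groups for w in g.wells]
        assert len(wells) == 96 and len(set(wells)) == 96
        assert all(len(g.wells) == 6 for g in canonical_layout.groups)

    def test_missing_control_reported(self, canonical_layout):
        layout = PlateLayout(
            format=canonical_layout.format,
            groups=[g for g in canonical_layout.groups if g.role is not Role.MO],
            staggered=False)
        assert any("missing control: MO" in v for v in pv.validate_layout(layout))

    def test_double_assignment_reported(self, canonical_layout):
        groups = [Group(g.label, g.role, list(g.wells), g.dose_Jcm2)
                  for g in canonical_layout.groups]
        groups[0].wells[0] = groups[1].wells[0]
        layout = PlateLayout(canonical_layout.format, groups, staggered=False)
        assert any("assigned twice" in v for v in pv.validate_layout(layout))

    def test_stagger_check_flags_adjacent_equal_doses(self):
        fmt = PlateFormat.plate96()
        groups = [
            Group("T1", Role.TREATMENT, ["A1", "A2", "A3", "B1", "B2", "B3"], 4.0),
            Group("T2", Role.TREATMENT, ["C1", "C2", "C3", "D1", "D2", "D3"], 4.0),
            Group("DNL", Role.DNL, ["A4", "A5", "A6", "B4", "B5", "B6"]),
            Group("LND", Role.LND, ["C4", "C5", "C6", "D4", "D5", "D6"]),
            Group("NDNL", Role.NDNL, ["E1", "E2", "E3", "F1", "F2", "F3"]),
            Group("MO", Role.MO, ["E4", "E5", "E6", "F4", "F5", "F6"]),
        ]
        layout = PlateLayout(fmt, groups, staggered=True)
        assert any("staggering" in v for v in pv.validate_layout(layout))
        layout.staggered = False
        assert pv.validate_layout(layout) == []

    def test_json_round_trip(self, tmp_path, canonical_layout):
        path = tmp_path / "layout.json"
        canonical_layout.to_json(path)
        back = PlateLayout.from_json(path)
        assert [g.label for g in back.groups] == \
            [g.label for g in canonical_layout.groups]
        assert back.group("PDT1-8J").dose_Jcm2 == 8.0


class TestMotion:
    def test_three_pitches(self):
        cfg = MotionConfig()  # 25 um/step
        mx, my = motion_steps((0.0, 0.0), (27.0, 0.0), cfg)
        assert (mx.steps, mx.direction) == (1080, 1)
        assert (my.steps, my.direction) == (0, 0)

    def test_no_move(self):
        mx, my = motion_steps((5.0, 5.0), (5.0, 5.0), MotionConfig())
        assert mx.steps == my.steps == 0

    def test_negative_direction(self):
        mx, _ = motion_steps((9.0, 0.0), (0.0, 0.0), MotionConfig())
        assert (mx.steps, mx.direction) == (360, -1)

    def test_residual_bounded_by_half_step(self):
        cfg = MotionConfig()
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = rng.uniform(0, 120, 2), rng.uniform(0, 120, 2)
            mx, my = motion_steps(tuple(a), tuple(b), cfg)
            assert abs(mx.residual_mm) <= cfg.step_size_um / 2000.0 + 1e-12
            assert abs(my.residual_mm) <= cfg.step_size_um / 2000.0 + 1e-12


class TestPlanning:
    def test_dose_series_total_time(self, canonical_layout):
        # two series over 2..12 J/cm^2 at exactly 50 mW/cm^2: the treatment
        # illumination sums to 2 * (2+4+6+8+10+12) / 0.05 = 1680 s
        calib = pv.IrradianceCalibration.linear(500.0)  # duty 0.10 -> 50
        plan = pv.plan_experiment(canonical_layout, 50.0, calib)
        treatment_time = sum(v.exposure_s for v in plan.visits
                             if v.group != "LND")
        assert treatment_time == pytest.approx(1680.0)
        # LND appended once, at the maximum treatment dose
        lnd = [v for v in plan.visits if v.group == "LND"]
        assert len(lnd) == 1 and lnd[0] is plan.visits[-1]
        assert lnd[0].dose_Jcm2 == 12.0
        assert plan.total_illumination_s == pytest.approx(1680.0 + 240.0)

    def test_visits_cover_each_dosed_group_once(self, canonical_layout):
        calib = pv.IrradianceCalibration.linear(500.0)
        plan = pv.plan_experiment(canonical_layout, 50.0, calib)
        visited = [v.group for v in plan.visits]
        dosed = [g.label for g in canonical_layout.groups
                 if g.role is Role.TREATMENT and g.dose_Jcm2 > 0]
        assert sorted(visited[:-1]) == sorted(dosed)
        assert len(visited) == len(set(visited))

    def test_single_group_plan(self):
        fmt = PlateFormat.plate96()
        groups = [
            Group("T", Role.TREATMENT, ["A1", "A2", "B1", "B2", "A3", "B3"], 8.0),
            Group("DNL", Role.DNL, ["C1", "C2", "C3", "D1", "D2", "D3"]),
            Group("LND", Role.LND, ["E1", "E2", "E3", "F1", "F2", "F3"]),
            Group("NDNL", Role.NDNL, ["G1", "G2", "G3", "H1", "H2", "H3"]),
            Group("MO", Role.MO, ["A4", "A5", "A6", "B4", "B5", "B6"]),
        ]
        layout = PlateLayout(fmt, groups, staggered=False)
        plan = pv.plan_experiment(layout, 100.0, pv.IrradianceCalibration.linear(400.0))
        t_visit = next(v for v in plan.visits if v.group == "T")
        assert t_visit.exposure_s == pytest.approx(80.0)

    def test_empty_dose_map_gives_controls_only_plan(self):
        fmt = PlateFormat.plate96()
        groups = [
            Group("DNL", Role.DNL, ["C1", "C2", "C3", "D1", "D2", "D3"]),
            Group("LND", Role.LND, ["E1", "E2", "E3", "F1", "F2", "F3"]),
            Group("NDNL", Role.NDNL, ["G1", "G2", "G3", "H1", "H2", "H3"]),
            Group("MO", Role.MO, ["A4", "A5", "A6", "B4", "B5", "B6"]),
        ]
        layout = PlateLayout(fmt, groups, staggered=False)
        plan = pv.plan_experiment(layout, 100.0, pv.IrradianceCalibration.linear(400.0))
        assert plan.visits == []
        assert plan.total_illumination_s == 0.0

    def test_unachievable_irradiance_names_group(self, canonical_layout):
        with pytest.raises(ValueError, match="group .*exceeds"):
            pv.plan_experiment(canonical_layout, 900.0,
                               pv.IrradianceCalibration.linear(400.0))

    def test_plan_csv_export(self, tmp_path, canonical_layout):
        import pandas as pd
        calib = pv.IrradianceCalibration.linear(500.0)
        plan = pv.plan_experiment(canonical_layout, 50.0, calib)
        path = tmp_path / "plan.csv"
        plan.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:4]) == ["visit", "group", "x_mm", "y_mm"]
        assert len(df) == len(plan.visits)
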