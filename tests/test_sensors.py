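"""Hill sensor responses, RPU conversion, and dose-response fitting."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fermlogic.sensors import (
    DEFAULT_CALIBRATION,
    DoseResponse,
    HillSensor,
    SensorCalibration,
    acetate_sensor,
    dynamic_range,
    fit_hill,
    glucose_sensor,
    low_oxygen_sensor,
    rpu_from_fluorescence,
    sensor_response,
)
from fermlogic.synth import generate_dose_response


class TestSensorResponse:
    @pytest.mark.parametrize(
        "sensor",
        [glucose_sensor(), acetate_sensor(), low_oxygen_sensor(),
         glucose_sensor(hill_n=2.7)],
        ids=["glucose", "acetate", "low_oxygen", "steep"],
    )
    def test_half_max_is_exact_midpoint_for_any_slope(self, sensor):
        mid = 0.5 * (sensor.y_min + sensor.y_max)
        assert sensor_response(sensor, sensor.ec50) == pytest.approx(mid, rel=1e-12)

    def test_zero_dose_limits(self):
        s = glucose_sensor()
        assert sensor_response(s, 0.0) == pytest.approx(s.y_min)
        d = low_oxygen_sensor()
        assert sensor_response(d, 0.0) == pytest.approx(d.y_max)

    def test_glucose_worked_example(self):
        # fold 18, ec50 0.1 %, n=1 at 0.4 %: 1/18 + (17/18)*0.8 = 0.8111
        assert sensor_response(glucose_sensor(), 0.4) == pytest.approx(
            0.8111, abs=1e-4
        )

    def test_negative_stimulus_rejected(self):
        with pytest.raises(ValueError):
            sensor_response(glucose_sensor(), -0.1)

    @given(
        s1=st.floats(0.0, 50.0),
        s2=st.floats(0.0, 50.0),
        n=st.floats(0.3, 6.0),
    )
    def test_monotone_in_stimulus(self, s1, s2, n):
        act = HillSensor("a", 0.1, 1.0, 5.0, n, "activating")
        dep = HillSensor("d", 0.1, 1.0, 5.0, n, "depletion_activating")
        lo, hi = sorted((s1, s2))
        assert act.response(lo) <= act.response(hi) + 1e-15
        assert dep.response(lo) >= dep.response(hi) - 1e-15

    @pytest.mark.parametrize(
        "kwargs",
        [dict(y_min=1.0, y_max=0.5), dict(ec50=-1.0), dict(hill_n=0.0),
         dict(mode="sideways")],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(name="x", y_min=0.1, y_max=1.0, ec50=1.0, hill_n=1.0,
                    mode="activating")
        base.update(kwargs)
        with pytest.raises(ValueError):
            HillSensor(**base)


class TestRpuConversion:
    @pytest.mark.parametrize("delta,expected", [(0.0, 0.0), (237.0, 0.237),
                                                (1346.0, 1.346)])
    def test_background_subtracted_scaling(self, delta, expected):
        assert rpu_from_fluorescence(1000.0 + delta, 1000.0) == pytest.approx(
            expected
        )

    @given(a=st.floats(0, 1e5), b=st.floats(0, 1e5), c=st.floats(1, 1e4))
    def test_linear_in_signal(self, a, b, c):
        # f(bg + a) + f(bg + b) == f(bg + a + b) for any background
        bg = c
        lhs = rpu_from_fluorescence(bg + a, bg) + rpu_from_fluorescence(bg + b, bg)
        rhs = rpu_from_fluorescence(bg + a + b, bg)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)

    def test_signal_below_background_rejected(self):
        with pytest.raises(ValueError):
            rpu_from_fluorescence(10.0, 20.0)

    def test_calibration_invariants(self):
        with pytest.raises(ValueError):
            SensorCalibration(rpu_conversion_factor=-1.0)
        with pytest.raises(ValueError):
            SensorCalibration(rpu_ranges={"x": (0.5, 0.1)})


class TestDynamicRange:
    @pytest.mark.parametrize(
        "sensor,fold",
        [(glucose_sensor(), 18.0), (low_oxygen_sensor(), 25.0),
         (acetate_sensor(), 250.0)],
        ids=["glucose", "low_oxygen", "acetate"],
    )
    def test_printed_folds(self, sensor, fold):
        assert dynamic_range(sensor) == pytest.approx(fold)

    def test_unit_fold_when_flat(self):
        s = HillSensor("flat-ish", 1.0, 1.0 + 1e-9, 1.0)
        assert dynamic_range(s) == pytest.approx(1.0)


class TestDoseResponseContainer:
    def test_csv_round_trip(self):
        dr = generate_dose_response(glucose_sensor(), [0, 0.05, 0.1, 0.4, 1.6],
                                    0.05, 3, seed=4)
        buf = io.StringIO(dr.to_csv_string())
        back = DoseResponse.from_csv(buf)
        np.testing.assert_allclose(back.doses, dr.doses)
        np.testing.assert_allclose(back.responses, dr.responses)

    def test_descending_doses_rejected(self):
        with pytest.raises(ValueError):
            DoseResponse(doses=[0.2, 0.1], responses=[[1.0], [2.0]])


class TestHillFit:
    @pytest.mark.parametrize(
        "sensor,top",
        [(glucose_sensor(), 1.6), (low_oxygen_sensor(), 210.0),
         (acetate_sensor(), 100.0)],
        ids=["glucose", "low_oxygen", "acetate"],
    )
    def test_noiseless_identity(self, sensor, top):
        doses = np.concatenate([[0.0], np.geomspace(top / 100, top, 11)])
        dr = generate_dose_response(sensor, doses, 0.0, 2, seed=0)
        rep = fit_hill(dr, mode=sensor.mode)
        assert not rep.poor_fit
        for got, want in [
            (rep.sensor.ec50, sensor.ec50),
            (rep.sensor.y_min, sensor.y_min),
            (rep.sensor.y_max, sensor.y_max),
            (rep.sensor.hill_n, sensor.hill_n),
        ]:
            assert got == pytest.approx(want, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        # 5 % CV, 3 replicates, 12 log-spaced doses to 10x ec50, fixed seed
        s = acetate_sensor()
        doses = np.concatenate([[0.0], np.geomspace(1.38, 138.0, 11)])
        dr = generate_dose_response(s, doses, 0.05, 3, seed=0)
        rep = fit_hill(dr, mode=s.mode)
        assert rep.sensor.ec50 == pytest.approx(s.ec50, rel=0.10)

    def test_model_mismatch_flagged(self):
        # decreasing (depletion-generated) data fitted with an activating model
        s = low_oxygen_sensor()
        doses = np.concatenate([[0.0], np.geomspace(2.1, 210.0, 11)])
        dr = generate_dose_response(s, doses, 0.05, 3, seed=1)
        assert fit_hill(dr, mode="activating").poor_fit

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_hill(DoseResponse([0.0, 1.0, 2.0], [[1.0], [2.0], [3.0]]))


class TestSerialization:
    def test_yaml_round_trip(self):
        s = low_oxygen_sensor(hill_n=1.5)
        back = HillSensor.from_yaml(s.to_yaml())
        assert back == s

    def test_default_calibration_ranges(self):
        assert DEFAULT_CALIBRATION.rpu_min("glucose") == pytest.approx(0.006)
        assert DEFAULT_CALIBRATION.rpu_max("low_oxygen") == pytest.approx(1.346)
        assert DEFAULT_CALIBRATION.rpu_max("acetate") == pytest.approx(0.700)
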