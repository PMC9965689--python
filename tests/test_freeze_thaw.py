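import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from frostprobe.calibration import CalibrationModel
from frostprobe.errors import DomainError, InsufficientDataError, MissingBaselineError
from frostprobe.freeze_thaw import (
    FreezeThawRecord,
    PipelineConfig,
    SensorReading,
    baseline_theta0,
    detect_frozen,
    format_rate_table,
    freeze_thaw_rate,
    ice_content,
    process_series,
    summarize_rates,
)

UTC = dt.timezone.utc
T0 = dt.datetime(2019, 1, 1, tzinfo=UTC)


def make_series(voltages, temps, minutes_step=1.0):
    return [
        SensorReading(timestamp=T0 + dt.timedelta(minutes=i * minutes_step),
                      U=u, temp=t)
        for i, (u, t) in enumerate(zip(voltages, temps))
    ]


def identity_model():
    # theta == U numerically: slope 1 %/V, zero intercept
    return CalibrationModel(species="id", slope_k=1.0, intercept_b=0.0, r_squared=1.0)


class TestDetectFrozen:
    def test_all_warm(self):
        assert not detect_frozen([20.0] * 5).any()

    def test_chamber_ramp_crossing(self):
        # 20 -> -16 C in 3 C steps: levels 20,17,...,2 above; -1,... at and below
        temps = np.arange(20.0, -16.0 - 1, -3.0)
        frozen = detect_frozen(temps)
        crossing = int(np.argmax(frozen))
        assert temps[crossing] == -1.0  # first level at or below 0 C
        assert not frozen[:crossing].any() and frozen[crossing:].all()

    def test_boundary_inclusive(self):
        assert detect_frozen([0.0])[0]

    def test_custom_threshold(self):
        assert detect_frozen([-1.0], freezing_point=-2.0)[0] == False  # noqa: E712


class TestBaseline:
    def test_constant_prefreeze(self):
        series = make_series([45.0] * 4 + [30.0], [5.0] * 4 + [-2.0])
        assert baseline_theta0(series, identity_model()) == pytest.approx(45.0)

    def test_window_mean(self):
        series = make_series([44.0, 45.0, 46.0, 20.0], [5.0, 5.0, 5.0, -2.0])
        assert baseline_theta0(series, identity_model()) == pytest.approx(45.0)

    def test_window_takes_last_samples_only(self):
        series = make_series([10.0, 44.0, 45.0, 46.0, 20.0],
                             [5.0, 5.0, 5.0, 5.0, -2.0])
        cfg = PipelineConfig(baseline_window=3)
        assert baseline_theta0(series, identity_model(), cfg) == pytest.approx(45.0)

    def test_all_frozen_errors(self):
        series = make_series([30.0, 29.0], [-5.0, -6.0])
        with pytest.raises(MissingBaselineError):
            baseline_theta0(series, identity_model())


class TestIceContent:
    def test_no_freezing(self):
        assert ice_content(45.0, 45.0) == 0.0

    def test_direct_arithmetic(self):
        # (45 - 30) * 0.917 = 13.755
        assert ice_content(45.0, 30.0, 0.917) == pytest.approx(13.755)

    def test_negative_clamped(self):
        assert ice_content(45.0, 50.0) == 0.0

    def test_negative_unclamped(self):
        assert ice_content(45.0, 50.0, clamp=False) == pytest.approx(-4.585)

    def test_domain(self):
        with pytest.raises(DomainError):
            ice_content(-1.0, 30.0)
        with pytest.raises(DomainError):
            ice_content(45.0, 101.0)


class TestFreezeThawRate:
    def ts(self, minutes):
        return [T0 + dt.timedelta(minutes=m) for m in minutes]

    def test_constant_delta(self):
        sigma = freeze_thaw_rate(self.ts([0, 1, 2]), [5.0, 5.0, 5.0])
        assert np.all(sigma == 0.0)

    def test_two_percent_per_minute(self):
        sigma = freeze_thaw_rate(self.ts([0, 1]), [10.0, 12.0])
        assert sigma[0] == pytest.approx(2.0)
        assert sigma[-1] == 0.0  # terminal convention

    def test_field_cadence(self):
        # 12 % -> 10 % over 10 min -> 0.2 %/min
        sigma = freeze_thaw_rate(self.ts([0, 10]), [12.0, 10.0])
        assert sigma[0] == pytest.approx(0.2)

    def test_duplicate_timestamps(self):
        with pytest.raises(DomainError):
            freeze_thaw_rate(self.ts([0, 0]), [1.0, 2.0])

    @given(deltas=st.lists(st.floats(min_value=0.0, max_value=50.0),
                           min_size=2, max_size=30))
    def test_nonnegative_and_time_reversal_invariant(self, deltas):
        ts = self.ts(range(len(deltas)))
        sigma = freeze_thaw_rate(ts, deltas)
        assert np.all(sigma >= 0.0)
        rev = freeze_thaw_rate(ts, deltas[::-1])
        # |forward difference| sequence of the reversed series is the mirror
        assert np.allclose(sigma[:-1], rev[:-1][::-1])


class TestProcessSeries:
    def test_never_frozen(self):
        series = make_series([45.0, 45.2, 44.8], [10.0, 8.0, 12.0])
        records = process_series(series, identity_model())
        assert all(r.delta == 0.0 and r.sigma == 0.0 and not r.frozen
                   for r in records)

    def test_single_sample(self):
        series = make_series([45.0], [10.0])
        records = process_series(series, identity_model())
        assert len(records) == 1 and records[0].delta == 0.0

    def test_chamber_shape(self):
        """Ice content rises during cooling, plateaus at deep frost, falls on thaw."""
        from frostprobe.synthetic_data import (
            CHAMBER_A, PhaseDynamicsParams, SimulationConfig, simulate_readings,
        )
        config = SimulationConfig(
            protocol=CHAMBER_A,
            dynamics=PhaseDynamicsParams(theta_total=45.0, rate_per_min=0.3),
            noise_sd_v=0.0, sample_minutes=1.0, seed=1,
        )
        readings, truth = simulate_readings(config, identity_model())
        records = process_series(readings, identity_model())
        delta = np.array([r.delta for r in records])
        frozen = np.array([r.frozen for r in records])
        onset = int(np.argmax(frozen))
        last = len(frozen) - 1 - int(np.argmax(frozen[::-1]))
        peak = delta.max()
        assert peak > 10.0
        assert delta[:onset].max() == 0.0
        mid = (onset + last) // 2
        assert delta[mid] > 0.75 * peak  # plateau near deep frost
        assert delta[last + 1:].max() == 0.0 if last + 1 < len(delta) else True
        # rising then falling around the plateau
        assert delta[onset + 5] > delta[onset]
        assert delta[last] < peak or math.isclose(delta[last], peak)

    def test_conservation_when_unclamped(self):
        series = make_series([45.0, 45.0, 45.0, 30.0, 20.0],
                             [5.0, 5.0, 5.0, -3.0, -6.0])
        cfg = PipelineConfig()
        records = process_series(series, identity_model(), cfg)
        theta0 = 45.0
        for r in records:
            if r.frozen:
                assert r.delta / cfg.density_ratio + r.theta_x == pytest.approx(theta0)
            assert r.delta <= theta0 * cfg.density_ratio + 1e-12

    def test_explicit_theta0_for_frozen_start(self):
        series = make_series([30.0, 25.0], [-5.0, -6.0])
        records = process_series(series, identity_model(), theta0=45.0)
        assert records[0].delta == pytest.approx((45.0 - 30.0) * 0.917)

    def test_frozen_start_without_theta0_errors(self):
        series = make_series([30.0, 25.0], [-5.0, -6.0])
        with pytest.raises(MissingBaselineError):
            process_series(series, identity_model())

    def test_rebaseline_on_second_freeze_event(self):
        # freeze, full thaw to a new baseline level, freeze again
        voltages = [45.0, 45.0, 30.0, 40.0, 40.0, 40.0, 35.0]
        temps = [5.0, 5.0, -3.0, 5.0, 5.0, 5.0, -3.0]
        records = process_series(make_series(voltages, temps), identity_model())
        assert records[2].delta == pytest.approx((45.0 - 30.0) * 0.917)
        # second event baselines on the 40 % plateau, not the original 45 %
        assert records[6].delta == pytest.approx((40.0 - 35.0) * 0.917)

    def test_non_increasing_timestamps_rejected(self):
        series = make_series([45.0, 44.0], [5.0, 5.0])
        bad = [series[0], SensorReading(series[0].timestamp, 44.0, 5.0)]
        with pytest.raises(DomainError):
            process_series(bad, identity_model())

    def test_deterministic(self):
        series = make_series([45.0, 45.0, 30.0], [5.0, 5.0, -3.0])
        a = process_series(series, identity_model())
        b = process_series(series, identity_model())
        assert a == b


class TestSummarizeRates:
    def recs(self, sigmas):
        return [
            FreezeThawRecord(timestamp=T0 + dt.timedelta(minutes=i), theta_x=0.0,
                             delta=0.0, sigma=s, frozen=False)
            for i, s in enumerate(sigmas)
        ]

    def test_constant(self):
        s = summarize_rates(self.recs([3.0, 3.0, 3.0]))
        assert s == {"mean": 3.0, "sd": 0.0, "min": 3.0, "max": 3.0}

    def test_hand_arithmetic(self):
        s = summarize_rates(self.recs([0.0, 2.0]))
        assert s["mean"] == pytest.approx(1.0)
        assert s["sd"] == pytest.approx(math.sqrt(2.0))
        assert s["min"] == 0.0
        assert s["max"] == 2.0

    def test_min_zero_with_zero_sample(self):
        s = summarize_rates(self.recs([0.5, 0.0, 0.7]))
        assert s["min"] == 0.0

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            summarize_rates(self.recs([1.0]))

    def test_table_labels(self):
        table = format_rate_table(summarize_rates(self.recs([0.0, 2.0])))
        for label in ("Mean Value", "Standard Deviation", "Minimum Value",
                      "Maximum Value"):
            assert label in table


class TestConfigValidation:
    def test_density_ratio_bounds(self):
        with pytest.raises(DomainError):
            PipelineConfig(density_ratio=0.0)
        with pytest.raises(DomainError):
            PipelineConfig(density_ratio=1.5)

    def test_baseline_window(self):
        with pytest.raises(DomainError):
            PipelineConfig(baseline_window=0)
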