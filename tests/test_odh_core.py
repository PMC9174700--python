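import numpy as np
import pytest

from flashodh import (
    ConfigurationError,
    LinearDepletionModel,
    LingDepletionModel,
    OxygenDoseHistogram,
    Pulse,
    PulseTrain,
    add,
    compose_train,
    dose_per_pulse,
    linear_trajectory,
    ling_trajectory,
    odh_from_trajectory,
    pulse_dose,
    scale,
)


class TestPulseDose:
    def test_rectangular_15_gy_in_3p4_us(self):
        # 15 Gy over 3400 ns -> 0.4412 cGy/ns instantaneous rate
        pulse = Pulse.rectangular(3400.0, 15.0 / 3400.0 / 0.01)
        assert pulse_dose(pulse) == pytest.approx(15.0, rel=1e-12)

    def test_from_dose_constructor_round_trips(self):
        pulse = Pulse.from_dose(1200.0, 22.5)
        assert pulse_dose(pulse) == pytest.approx(22.5, rel=1e-12)

    def test_short_pulse_limit(self):
        pulse = Pulse.rectangular(1e-9, 1.0)
        assert pulse_dose(pulse) == pytest.approx(0.0, abs=1e-9)

    def test_triangular_shape_half_area(self):
        peak = 0.5  # cGy/ns
        length = 2000.0
        times = np.linspace(0.0, length, 2001)
        rates = peak * (1.0 - np.abs(times - length / 2) / (length / 2))
        pulse = Pulse(length_l=length, rate_shape=(times, rates))
        assert pulse_dose(pulse) == pytest.approx(
            length * peak / 2 * 0.01, rel=1e-6
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            Pulse.rectangular(100.0, -1.0)


class TestDosePerPulse:
    @pytest.mark.parametrize(
        "rate, prf, expected",
        [(100.0, 100.0, 1.0), (0.1, 100.0, 0.001), (250.0, 250.0, 1.0)],
    )
    def test_division_convention(self, rate, prf, expected):
        assert dose_per_pulse(rate, prf) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_prf_rejected(self):
        with pytest.raises(ValueError):
            dose_per_pulse(10.0, 0.0)


class TestOdhFromTrajectory:
    def test_linear_example_bin_pattern(self, fig2_model):
        # 7 Torr at 0.6 Torr/Gy over 15 Gy with 1-Torr bins: each traversed
        # bin gets 1/0.6 Gy, the hypoxic bin additionally the post-onset dose.
        traj = linear_trajectory(fig2_model, 15.0)
        hist = odh_from_trajectory(traj, bin_width=1.0)
        per_bin = 1.0 / 0.6
        expected = np.array([per_bin + (15.0 - 7.0 / 0.6)] + [per_bin] * 6 + [0.0])
        np.testing.assert_allclose(hist.doses, expected, rtol=1e-12)
        assert hist.total_dose == pytest.approx(15.0, rel=1e-12)

    def test_constant_trajectory_single_bin(self):
        traj = linear_trajectory(LinearDepletionModel(7.0, 0.0), 10.0)
        hist = odh_from_trajectory(traj, bin_width=1.0)
        assert hist.doses[7] == pytest.approx(10.0, rel=1e-12)
        assert hist.total_dose == pytest.approx(10.0, rel=1e-12)
        assert np.count_nonzero(hist.doses) == 1

    def test_explicit_edges_must_cover(self, fig2_model):
        traj = linear_trajectory(fig2_model, 15.0)
        with pytest.raises(ConfigurationError):
            odh_from_trajectory(traj, edges=np.array([0.0, 2.0, 5.0]))

    def test_ling_trajectory_conserves_dose(self, ling_model):
        traj = ling_trajectory(ling_model, pulse_length=3400.0)
        hist = odh_from_trajectory(traj, bin_width=0.1)
        assert hist.total_dose == pytest.approx(ling_model.dose_d, rel=1e-9)


class TestHistogramAlgebra:
    @pytest.fixture
    def odh_a(self, fig2_model):
        return odh_from_trajectory(linear_trajectory(fig2_model, 15.0), bin_width=1.0)

    def test_addition_identity(self, odh_a):
        empty = OxygenDoseHistogram(odh_a.edges, np.zeros_like(odh_a.doses))
        assert add(odh_a, empty) == odh_a

    def test_self_addition_equals_scaling(self, odh_a):
        doubled = add(odh_a, odh_a)
        np.testing.assert_allclose(doubled.doses, scale(odh_a, 2.0).doses, rtol=1e-12)

    def test_commutative_across_different_grids(self, odh_a):
        other = odh_from_trajectory(
            linear_trajectory(LinearDepletionModel(5.5, 0.3), 4.0), bin_width=0.4
        )
        ab, ba = add(odh_a, other), add(other, odh_a)
        np.testing.assert_allclose(ab.doses, ba.doses, rtol=1e-12)
        assert ab.total_dose == pytest.approx(
            odh_a.total_dose + other.total_dose, rel=1e-12
        )

    def test_associative_up_to_rebinning(self, odh_a):
        b = odh_from_trajectory(
            linear_trajectory(LinearDepletionModel(3.0, 0.25), 2.0), bin_width=0.3
        )
        c = odh_from_trajectory(
            linear_trajectory(LinearDepletionModel(6.0, 1.0), 7.0), bin_width=0.7
        )
        left = add(add(odh_a, b), c)
        right = add(odh_a, add(b, c))
        np.testing.assert_allclose(left.doses, right.doses, rtol=1e-12, atol=1e-15)

    def test_scale_inverse(self, odh_a):
        back = scale(add(odh_a, odh_a), 0.5)
        np.testing.assert_allclose(back.doses, odh_a.doses, rtol=1e-12)

    def test_scale_rejects_nonpositive(self, odh_a):
        with pytest.raises(ValueError):
            scale(odh_a, 0.0)

    def test_csv_round_trip(self, odh_a, tmp_path):
        path = tmp_path / "odh.csv"
        odh_a.to_csv(path)
        back = OxygenDoseHistogram.from_csv(path)
        np.testing.assert_allclose(back.edges, odh_a.edges)
        np.testing.assert_allclose(back.doses, odh_a.doses)


class TestComposeTrain:
    def test_full_reoxygenation_scales_single_pulse(self):
        model = LinearDepletionModel(152.0, 15.0)
        pulse = Pulse.from_dose(1200.0, 7.5)
        single = compose_train(PulseTrain(pulse=pulse, count=1), model)
        double = compose_train(
            PulseTrain(pulse=pulse, count=2, period=2.5, reoxygenation="full"), model
        )
        np.testing.assert_allclose(double.doses, 2.0 * single.doses, rtol=1e-12)

    def test_no_reoxygenation_equals_one_long_pulse(self):
        model = LinearDepletionModel(20.0, 2.0)
        pulse = Pulse.from_dose(1000.0, 2.0)
        train = compose_train(
            PulseTrain(pulse=pulse, count=5, period=10.0, reoxygenation="none"), model
        )
        one_pulse = compose_train(
            PulseTrain(pulse=Pulse.from_dose(5000.0, 10.0), count=1), model
        )
        np.testing.assert_allclose(train.doses, one_pulse.doses, rtol=1e-9, atol=1e-12)

    def test_partial_fraction_endpoints_match_full_and_none(self):
        model = LinearDepletionModel(20.0, 2.0)
        pulse = Pulse.from_dose(1000.0, 3.0)

        def train(reox, f=1.0):
            return compose_train(
                PulseTrain(
                    pulse=pulse, count=3, period=10.0, reoxygenation=reox, fraction=f
                ),
                model,
            )

        np.testing.assert_allclose(
            train("partial", 1.0).doses, train("full").doses, rtol=1e-12
        )
        np.testing.assert_allclose(
            train("partial", 0.0).doses, train("none").doses, rtol=1e-12
        )

    def test_ling_train_conserves_dose(self):
        model = LingDepletionModel(o2_0=20.0, g_yield=1.0, dose_d=2.0, lam=5e-4)
        pulse = Pulse.from_dose(1800.0, 2.0)
        train = PulseTrain(pulse=pulse, count=4, period=10.0, reoxygenation="partial", fraction=0.5)
        hist = compose_train(train, model)
        assert hist.total_dose == pytest.approx(8.0, rel=1e-9)

    def test_period_shorter_than_pulse_rejected(self):
        pulse = Pulse.from_dose(2e6, 1.0)  # 2 ms pulse
        with pytest.raises(ConfigurationError):
            PulseTrain(pulse=pulse, count=2, period=1.0)
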