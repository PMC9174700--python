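import numpy as np
import pytest
from scipy.integrate import quad

from flashodh import (
    LinearDepletionModel,
    OxygenDoseHistogram,
    correct_survival,
    crossover_dose,
    linear_sparing_factor,
    linear_total_damage,
    linear_trajectory,
    odh_from_trajectory,
    oxygen_response,
    sparing_factor,
    sparing_vs_dose,
    sparing_vs_o2,
    total_damage,
)


def quad_damage(o2_0, rate, dose, response):
    """Adaptive-quadrature oracle for the trajectory damage integral."""
    model = LinearDepletionModel(o2_0, rate)
    traj = linear_trajectory(model, dose)

    def integrand(d):
        return oxygen_response(traj.o2_at(d), response)

    val, err = quad(integrand, 0.0, dose, points=list(traj.doses), limit=200)
    assert err < 1e-10 * max(val, 1.0)
    return val


class TestTotalDamage:
    def test_single_bin_histogram(self, response):
        hist = OxygenDoseHistogram([0.0, 7.0, 7.5], [0.0, 10.0])
        expected = 10.0 * oxygen_response(7.25, response)
        assert total_damage(hist, response) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_linear_integral_value(self, response):
        # Hand-checkable: (1/R)[C1*do2 - (C1*C3 - C2) ln((o2_0+C3)/C3)]
        # + hypoxic remainder * C2/C3 at o2_0=2, R=0.42, D=10.
        assert linear_total_damage(2.0, 0.42, 10.0, response) == pytest.approx(
            31.97, rel=1e-3
        )

    def test_closed_form_matches_quadrature(self, response):
        for o2_0, rate, dose in [(2.0, 0.42, 10.0), (20.0, 0.42, 30.0), (152.0, 15.0, 15.0)]:
            closed = linear_total_damage(o2_0, rate, dose, response)
            assert closed == pytest.approx(
                quad_damage(o2_0, rate, dose, response), rel=1e-9
            )

    def test_binned_converges_to_closed_form(self, response):
        model = LinearDepletionModel(2.0, 0.42)
        closed = linear_total_damage(2.0, 0.42, 10.0, response)
        hist = odh_from_trajectory(linear_trajectory(model, 10.0), bin_width=0.01)
        assert total_damage(hist, response) == pytest.approx(closed, rel=1e-3)

    def test_linearity_in_dose_scale(self, response):
        model = LinearDepletionModel(5.0, 0.5)
        hist = odh_from_trajectory(linear_trajectory(model, 8.0), bin_width=0.05)
        doubled = OxygenDoseHistogram(hist.edges, 2.0 * hist.doses)
        assert total_damage(doubled, response) == pytest.approx(
            2.0 * total_damage(hist, response), rel=1e-12
        )


class TestSparingFactor:
    def test_no_depletion_gives_exactly_one(self, response):
        hist = odh_from_trajectory(
            linear_trajectory(LinearDepletionModel(7.0, 0.0), 10.0), bin_width=1.0
        )
        # Degenerate single-bin histogram evaluated at its midpoint: force
        # the midpoint onto the initial level by a fine grid around it.
        assert linear_sparing_factor(7.0, 0.0, 10.0, response) == 1.0
        res = sparing_factor(hist, hist.midpoints[np.argmax(hist.doses)], response)
        assert res.factor == pytest.approx(1.0, rel=1e-12)

    def test_reference_scenario_value(self, response):
        assert linear_sparing_factor(2.0, 0.42, 10.0, response) == pytest.approx(
            0.7509, abs=2e-4
        )

    def test_high_dose_asymptote(self, response):
        limit = oxygen_response(0.0, response) / oxygen_response(20.0, response)
        assert limit == pytest.approx(0.3963, abs=1e-4)
        got = linear_sparing_factor(20.0, 15.0, 1e4, response)
        assert got == pytest.approx(limit, rel=5e-3)

    def test_zero_dose_histogram_rejected(self, response):
        hist = OxygenDoseHistogram([0.0, 1.0], [0.0])
        with pytest.raises(ValueError):
            sparing_factor(hist, 1.0, response)

    def test_factor_bounds(self, response):
        # factor in (F(0)/F(o2_0), 1] for any finite dose
        for dose in (0.1, 1.0, 10.0, 100.0, 1e4):
            f = linear_sparing_factor(20.0, 0.42, dose, response)
            lo = oxygen_response(0.0, response) / oxygen_response(20.0, response)
            assert lo < f <= 1.0


class TestCorrectSurvival:
    @pytest.mark.parametrize(
        "sf, factor, expected",
        [(0.1, 0.5, 0.55), (0.3, 1.0, 0.3), (1.0, 0.2, 1.0)],
    )
    def test_examples(self, sf, factor, expected):
        assert correct_survival(sf, factor) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_both_arguments(self):
        sfs = np.linspace(0.0, 1.0, 21)
        assert np.all(np.diff(correct_survival(sfs, 0.5)) > 0)
        factors = np.linspace(0.1, 1.0, 19)
        assert np.all(np.diff(correct_survival(0.2, factors)) < 0)

    def test_result_never_below_measurement(self, rng):
        sf = rng.uniform(0.0, 1.0, 100)
        f = rng.uniform(0.01, 1.0, 100)
        out = correct_survival(sf, f)
        assert np.all(out >= sf - 1e-15)
        assert np.all(out <= 1.0 + 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correct_survival(1.2, 0.5)
        with pytest.raises(ValueError):
            correct_survival(0.5, 0.0)


class TestSweeps:
    def test_sparing_vs_dose_non_increasing(self, response):
        model = LinearDepletionModel(20.0, 0.42)
        table = sparing_vs_dose(20.0, model, np.geomspace(0.1, 1e3, 40), response)
        assert np.all(np.diff(table["sparing_factor"]) <= 1e-12)

    def test_zero_rate_sweep_is_all_ones(self, response):
        model = LinearDepletionModel(20.0, 0.0)
        table = sparing_vs_o2(15.0, model, np.linspace(0.0, 20.0, 11), response)
        np.testing.assert_allclose(table["sparing_factor"], 1.0, rtol=1e-12)

    def test_low_dose_ordering_favours_low_oxygen(self, response):
        # At 2 Gy the 2 Torr tissue is spared more than the 20 Torr tissue.
        model = LinearDepletionModel(2.0, 0.42)
        f2 = linear_sparing_factor(2.0, 0.42, 2.0, response)
        f20 = linear_sparing_factor(20.0, 0.42, 2.0, response)
        assert f2 < f20

    def test_binned_path_agrees_with_closed_form(self, response):
        model = LinearDepletionModel(10.0, 0.6)
        doses = np.array([1.0, 5.0, 25.0])
        closed = sparing_vs_dose(10.0, model, doses, response)
        binned = sparing_vs_dose(10.0, model, doses, response, bin_width=0.01)
        np.testing.assert_allclose(
            closed["sparing_factor"], binned["sparing_factor"], rtol=1e-3
        )


class TestCrossover:
    @pytest.mark.parametrize("rate", [0.22, 0.42, 15.0])
    def test_unique_crossover_exists_for_2_vs_20_torr(self, rate, response):
        model = LinearDepletionModel(2.0, rate)
        d = crossover_dose(2.0, 20.0, model, response=response)
        assert d is not None and d > 0
        # sign change verified around the root
        eps = max(1e-3, 1e-6 * d)
        below = linear_sparing_factor(2.0, rate, d - eps, response) - \
            linear_sparing_factor(20.0, rate, d - eps, response)
        above = linear_sparing_factor(2.0, rate, d + eps, response) - \
            linear_sparing_factor(20.0, rate, d + eps, response)
        assert below * above < 0

    def test_symmetric_in_arguments(self, response):
        model = LinearDepletionModel(2.0, 0.42)
        d_ab = crossover_dose(2.0, 20.0, model, response=response)
        d_ba = crossover_dose(20.0, 2.0, model, response=response)
        assert d_ab == pytest.approx(d_ba, abs=1e-5)

    def test_identical_levels_signal_no_crossover(self, response):
        model = LinearDepletionModel(2.0, 0.42)
        assert crossover_dose(5.0, 5.0, model, response=response) is None
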