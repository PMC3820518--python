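"""Generalized filtering: errors, updates, convergence, oddball inference."""

import numpy as np
import pytest

from mmnsim.generalized import GeneralizedVector, embed
from mmnsim.gfilter import (
    BeliefState,
    FilterDivergenceError,
    GeneralizedFilter,
    StaticLinearModel,
    filter_run,
    gf_step,
    prediction_errors,
)
from mmnsim.hdm import AuditoryHDM, OddballCondition
from mmnsim.stimulus import generate_stimulus


def static_belief(model, value, order=2):
    mu_v = np.zeros((order, model.n_causes))
    mu_v[0] = value
    return BeliefState(GeneralizedVector(np.zeros((order, 0))),
                       GeneralizedVector(mu_v))


class TestPredictionErrors:
    def test_zero_when_belief_generates_the_data(self):
        m = StaticLinearModel(eta=2.0, pi_y=3.0, pi_v=1.5)
        belief = static_belief(m, 2.0)
        y_tilde = GeneralizedVector(np.array([[2.0], [0.0]]))
        eps, xi = prediction_errors(belief, y_tilde, m)
        for stream in ("sensory", "states", "causes"):
            np.testing.assert_allclose(xi[stream], 0.0, atol=1e-12)

    def test_doubling_precision_doubles_weighted_errors(self):
        y_tilde = GeneralizedVector(np.array([[3.0], [0.0]]))
        m1 = StaticLinearModel(eta=1.0, pi_y=2.0, pi_v=0.5)
        m2 = StaticLinearModel(eta=1.0, pi_y=4.0, pi_v=1.0)
        belief = static_belief(m1, 1.4)
        eps1, xi1 = prediction_errors(belief, y_tilde, m1)
        eps2, xi2 = prediction_errors(belief, y_tilde, m2)
        np.testing.assert_allclose(eps1["sensory"], eps2["sensory"])
        np.testing.assert_allclose(2 * xi1["sensory"], xi2["sensory"])
        np.testing.assert_allclose(2 * xi1["causes"], xi2["causes"])

    def test_scalar_model_matches_hand_computation(self):
        # order-1 embedding: no smoothness coupling, xi = pi * eps exactly
        m = StaticLinearModel(eta=1.0, pi_y=2.0, pi_v=0.5)
        belief = static_belief(m, 1.4, order=1)
        y_tilde = GeneralizedVector(np.array([[3.0]]))
        eps, xi = prediction_errors(belief, y_tilde, m, order_causes=1)
        assert eps["sensory"][0, 0] == pytest.approx(3.0 - 1.4)
        assert xi["sensory"][0, 0] == pytest.approx(2.0 * (3.0 - 1.4))
        assert eps["causes"][0, 0] == pytest.approx(1.4 - 1.0)
        assert xi["causes"][0, 0] == pytest.approx(0.5 * (1.4 - 1.0))


class TestGfStep:
    def test_no_error_fixed_point_is_stationary(self):
        m = StaticLinearModel(eta=2.0, pi_y=3.0, pi_v=1.5)
        belief = static_belief(m, 2.0)
        y_tilde = GeneralizedVector(np.array([[2.0], [0.0]]))
        out = gf_step(belief, y_tilde, m, dt=0.05)
        np.testing.assert_allclose(out.flatten(), belief.flatten(), atol=1e-12)

    def test_fixed_point_is_precision_weighted_average(self):
        m = StaticLinearModel(eta=1.0, pi_y=4.0, pi_v=2.0)
        gf = GeneralizedFilter(m, order_states=2, order_causes=2)
        y = 3.0
        data = np.full((300, 1), y)
        res = gf.run(data, np.arange(300) * 0.05)
        expected = (4.0 * y + 2.0 * 1.0) / 6.0
        assert res.mu_v[-1, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_step_descends_the_squared_error_on_static_input(self):
        m = StaticLinearModel(eta=0.0, pi_y=1.0, pi_v=1.0)
        gf = GeneralizedFilter(m, order_states=2, order_causes=2)
        belief = static_belief(m, 0.0)
        y_tilde = GeneralizedVector(np.array([[2.0], [0.0]]))
        before = gf.squared_error(belief, y_tilde, 0.0)
        after = gf.squared_error(gf.step(belief, y_tilde, 0.0, 1e-3), y_tilde, 0.0)
        assert after < before

    def test_divergence_raises_with_diagnostics(self):
        m = StaticLinearModel(eta=0.0, pi_y=1.0, pi_v=1.0)
        gf = GeneralizedFilter(m, order_states=2, order_causes=2, divergence_norm=1e-9)
        belief = static_belief(m, 0.0)
        y_tilde = GeneralizedVector(np.array([[2.0], [0.0]]))
        with pytest.raises(FilterDivergenceError) as exc:
            gf.step(belief, y_tilde, 0.0, 0.1)
        assert exc.value.bound == 1e-9

    def test_rejects_nonpositive_dt(self):
        m = StaticLinearModel(eta=0.0, pi_y=1.0, pi_v=1.0)
        gf = GeneralizedFilter(m, order_states=2, order_causes=2)
        with pytest.raises(ValueError):
            gf.step(static_belief(m, 0.0), GeneralizedVector(np.zeros((2, 1))), 0.0, 0.0)


@pytest.fixture(scope="module")
def deviant_runs(config):
    """Filter runs for deviants of increasing magnitude at p = 0.05."""
    out = {}
    for mag in (0.02, 0.04, 0.27, 0.32):
        cond = OddballCondition(1000.0, mag, 0.05)
        stim, truth = generate_stimulus(cond, config, 0)
        model = AuditoryHDM.for_recognition(config, cond)
        res = filter_run(stim, model, gradient_rate=config.filter.gradient_rate)
        out[mag] = (res, truth, model)
    return out


class TestFilterRun:
    def test_standard_prior_produces_less_cause_error_than_deviant(self, config, deviant_runs):
        cond = OddballCondition(1000.0, 0.32, 0.05, trial_type="standard")
        stim, _ = generate_stimulus(cond, config, 0)
        model = AuditoryHDM.for_recognition(config, cond)
        res_std = filter_run(stim, model, gradient_rate=config.filter.gradient_rate)
        res_dev = deviant_runs[0.32][0]
        peak_std = np.abs(res_std.errors.xi_causes[:, 1]).max()
        peak_dev = np.abs(res_dev.errors.xi_causes[:, 1]).max()
        assert peak_std < 0.2 * peak_dev

    def test_deviant_frequency_correctly_inferred_then_released(self, config, deviant_runs):
        res, truth, model = deviant_runs[0.32]
        e = config.envelope
        plateau = (res.times >= e.peak_time) & (res.times <= e.peak_time + e.width)
        mu_nu = res.mu_v[:, 0, 1]
        spacing = abs(truth.target_log_frequency - model.prior_mean_freq)
        assert np.abs(mu_nu[plateau] - truth.target_log_frequency).max() < 0.05 * spacing
        # after offset the belief returns toward the prior mean
        assert abs(mu_nu[-1] - model.prior_mean_freq) < 0.2 * spacing

    def test_peak_errors_nondecreasing_in_magnitude(self, deviant_runs):
        # at small magnitudes the sensory peak sits on a magnitude-independent
        # floor set by the loudness transient, so equality (within 0.5%) counts
        mags = sorted(deviant_runs)
        sens = np.array([np.abs(deviant_runs[m][0].errors.xi_sensory).max() for m in mags])
        caus = np.array([np.abs(deviant_runs[m][0].errors.xi_causes[:, 1]).max() for m in mags])
        assert np.all(sens[1:] >= 0.995 * sens[:-1])
        assert np.all(np.diff(caus) > 0)

    def test_monotone_prior_precision_effect(self, config):
        cond = OddballCondition(1000.0, 0.127, 0.05)
        stim, _ = generate_stimulus(cond, config, 0)
        peaks = []
        for prec in (10.0, 30.0, 100.0, 300.0):
            model = AuditoryHDM.for_recognition(config, cond)
            model.prior_precision_freq = prec
            res = filter_run(stim, model, gradient_rate=config.filter.gradient_rate)
            peaks.append(np.abs(res.errors.xi_causes[:, 1]).max())
        assert np.all(np.diff(peaks) > 0)

    def test_identical_inputs_give_identical_trajectories(self, config):
        cond = OddballCondition(1000.0, 0.127, 0.05)
        stim, _ = generate_stimulus(cond, config, 5)
        model = AuditoryHDM.for_recognition(config, cond)
        r1 = filter_run(stim, model, gradient_rate=config.filter.gradient_rate)
        r2 = filter_run(stim, model, gradient_rate=config.filter.gradient_rate)
        np.testing.assert_array_equal(r1.mu_v, r2.mu_v)
        np.testing.assert_array_equal(r1.errors.xi_sensory, r2.errors.xi_sensory)

    def test_squared_error_diagnostic_is_finite_and_nonnegative(self, deviant_runs):
        res = deviant_runs[0.127 if 0.127 in deviant_runs else 0.27][0]
        assert np.all(np.isfinite(res.squared_error))
        assert np.all(res.squared_error >= 0)


def test_embedded_data_matches_direct_embedding(config):
    cond = OddballCondition(1000.0, 0.127, 0.05)
    stim, _ = generate_stimulus(cond, config, 2)
    gv = embed(stim.channels, 100, 4, stim.dt)
    assert gv.embedding_order == 4
    assert gv.dim == 50
    # value order reproduces the sample itself up to interpolation error
    np.testing.assert_allclose(gv.orders[0], stim.channels[100], atol=1e-6)
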