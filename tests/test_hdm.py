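"""The auditory generative model: tuning, dynamics, priors, configuration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mmnsim.config import ModelConfig
from mmnsim.hdm import (
    AuditoryHDM,
    OddballCondition,
    TuningBank,
    flow,
    generate_observation,
    prior_precision_from_probability,
    spectral_response,
)


@pytest.fixture(scope="module")
def bank(config):
    return TuningBank.around(1000.0, config)


@pytest.fixture(scope="module")
def model(config):
    cond = OddballCondition(1000.0, 0.127, 0.1)
    return AuditoryHDM.for_recognition(config, cond)


class TestSpectralResponse:
    def test_unit_gain_at_preferred_frequency(self, bank):
        lf = bank.preferred_log_frequencies[17]
        resp = spectral_response(lf, 2.5, bank)
        assert resp[17] == pytest.approx(2.5)
        assert resp.argmax() == 17

    def test_zero_loudness_silences_all_channels(self, bank):
        np.testing.assert_array_equal(spectral_response(6.9, 0.0, bank), np.zeros(50))

    def test_symmetry_about_equidistant_channels(self, bank):
        nu = bank.preferred_log_frequencies
        mid = 0.5 * (nu[10] + nu[11])
        resp = spectral_response(mid, 1.0, bank)
        assert resp[10] == pytest.approx(resp[11], rel=1e-12)

    def test_nonnegative_and_loudness_proportional_integral(self, bank):
        # Gaussian tuning: integral over log-frequency = loudness * w * sqrt(2 pi)
        grid = np.linspace(bank.preferred_log_frequencies[0] - 2,
                           bank.preferred_log_frequencies[-1] + 2, 4000)
        for loud in (0.5, 2.0):
            resp = np.array([spectral_response(g, loud, bank) for g in grid])
            assert (resp >= 0).all()
            integral = np.trapezoid(resp[:, 25], grid)
            assert integral == pytest.approx(
                loud * bank.tuning_width * np.sqrt(2 * np.pi), rel=1e-4
            )

    def test_rejects_non_finite(self, bank):
        with pytest.raises(ValueError):
            spectral_response(np.inf, 1.0, bank)


class TestFlow:
    def test_frequency_fixed_point(self, model):
        x = np.array([0.3, -0.1, 6.9])
        v = np.array([0.5, 6.9])
        assert flow(x, v, model)[2] == 0.0

    def test_origin_is_loudness_attractor(self, model):
        dx = flow(np.zeros(3), np.zeros(2), model)
        np.testing.assert_array_equal(dx[:2], [0.0, 0.0])

    def test_loudness_spirals_to_zero(self, model, config):
        # eigenvalues: complex pair with negative real part
        eig = np.linalg.eigvals(model.loudness_matrix)
        assert np.all(eig.real < 0) and np.all(eig.imag != 0)
        # integrated impulse response decays below 1% of its peak within
        # the documented horizon of 1.0 native time units
        dt = 1e-3
        x = np.array([1.0, 0.0, 0.0])
        traj = []
        for _ in range(int(1.0 / dt)):
            traj.append(x[0])
            x = x + dt * flow(x, np.zeros(2), model)
        traj = np.abs(np.array(traj))
        assert traj[-1] < 0.01 * traj.max()
        # oscillation: the loudness state changes sign at least once
        assert (np.sign(np.array(traj[:-1])) != 0).any()

    def test_drive_steady_state_tracks_cause(self, model):
        # DC gain of the driven oscillator is 1: f(x*, v) = 0 at x_l = v_l
        v = np.array([0.7, model.prior_mean_freq])
        x_star = np.array([0.7, 0.0, model.prior_mean_freq])
        np.testing.assert_allclose(flow(x_star, v, model), np.zeros(3), atol=1e-12)


class TestPriorPrecision:
    def test_documented_mapping_value(self):
        # precision(p) = floor + scale * (-ln p), recomputed independently
        p = 0.05
        assert prior_precision_from_probability(p, 1.0, 32.0) == pytest.approx(
            1.0 + 32.0 * -np.log(0.05)
        )

    def test_approaches_floor_as_p_to_one(self):
        assert prior_precision_from_probability(1 - 1e-12, 1.0, 32.0) == pytest.approx(1.0)

    @given(st.tuples(
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
    ))
    def test_strictly_decreasing_and_positive(self, ps):
        p1, p2 = sorted(ps)
        f1, f2 = (prior_precision_from_probability(p) for p in (p1, p2))
        assert f1 > 0 and f2 > 0
        if p1 < p2:
            assert f1 > f2

    def test_continuity_on_a_fine_grid(self):
        # dense in log-p so the steep small-p region is resolved too
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1 - 1e-4), 4000))
        vals = np.array([prior_precision_from_probability(p) for p in grid])
        assert np.all(np.diff(vals) < 0)
        # increments shrink with the grid: no jump exceeds the local slope bound
        slope = 32.0 / grid[:-1]
        assert np.all(np.abs(np.diff(vals)) <= slope * np.diff(grid) + 1e-9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_rejects_probabilities_outside_unit_interval(self, p):
        with pytest.raises(ValueError):
            prior_precision_from_probability(p)


class TestGenerateObservation:
    def test_zero_loudness_readout_gives_zero_vector(self, model):
        np.testing.assert_array_equal(
            generate_observation(np.array([0.0, 1.0, 6.9]), model), np.zeros(50)
        )

    def test_composition_with_spectral_response(self, model):
        x = np.array([0.8, 0.0, 6.95])
        np.testing.assert_array_equal(
            generate_observation(x, model),
            spectral_response(6.95, 0.8, model.tuning),
        )

    def test_finite_for_finite_states(self, model):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 5, 3)
            assert np.all(np.isfinite(generate_observation(x, model)))

    def test_jacobian_matches_finite_differences(self, model):
        x = np.array([0.6, -0.2, 6.95])
        Gx, _ = model.g_jac(x, np.zeros(2))
        h = 1e-7
        for j in range(3):
            xp = x.copy()
            xp[j] += h
            fd = (generate_observation(xp, model) - generate_observation(x, model)) / h
            np.testing.assert_allclose(Gx[:, j], fd, atol=1e-5)


class TestValidation:
    def test_tuning_bank_requires_50_increasing_channels(self):
        with pytest.raises(ValueError):
            TuningBank(np.linspace(7, 6, 50), 0.1)
        with pytest.raises(ValueError):
            TuningBank(np.linspace(6, 7, 49), 0.1)

    def test_condition_bounds(self):
        with pytest.raises(ValueError):
            OddballCondition(-1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            OddballCondition(1000.0, 0.1, 0.0)

    def test_loudness_matrix_must_spiral(self, config):
        cond = OddballCondition(1000.0, 0.1, 0.1)
        m = AuditoryHDM.for_recognition(config, cond)
        with pytest.raises(ValueError):
            AuditoryHDM(
                tuning=m.tuning, kappa_freq=m.kappa_freq,
                loudness_matrix=np.array([[1.0, 0.0], [0.0, 1.0]]),  # expanding
                loudness_drive=m.loudness_drive,
                obs_log_precision=1.0, state_log_precision=1.0,
                cause_log_precisions=np.zeros(2), smoothness=0.04,
                prior_mean_freq=6.9, prior_precision_freq=1.0,
                envelope_peak_time=1.0, envelope_width=0.3, envelope_amplitude=1.0,
            )


def test_config_round_trip(tmp_path, config):
    path = tmp_path / "model.yaml"
    config.save(path)
    loaded = ModelConfig.load(path)
    assert loaded == config


def test_config_rejects_unknown_keys(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("tuning:\n  n_channles: 50\n")
    with pytest.raises(KeyError):
        ModelConfig.load(path)
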