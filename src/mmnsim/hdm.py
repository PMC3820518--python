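"""The three-level auditory hierarchical dynamic model (HDM).

Level 1 (primary auditory cortex, A1): the sensory prediction is a
spectrogram — 50 loudness-modulated frequency channels with Gaussian
tonotopic tuning in log-frequency.

Level 2 (lateral Heschl's gyrus): hidden states are the instantaneous
loudness ``(x_l, x_l')`` — a damped linear oscillator driven by the loudness
cause — and the instantaneous log-frequency ``x_nu``, which relaxes towards
the target log-frequency at rate ``kappa``.

Level 3 (inferior frontal gyrus): hidden causes ``(v_l, v_nu)`` — the
loudness envelope and the target log-frequency — with Gaussian priors.  The
prior precision on the target frequency encodes how confidently a standard
tone is expected, i.e. the deviant probability of the oddball stream.

The same model generates stimuli (with near-deterministic noise precisions)
and serves as the listener's internal model during recognition (with
epistemic, lower precisions and a prior centred on the expected tone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .config import ModelConfig

__all__ = [
    "TuningBank",
    "AuditoryHDM",
    "OddballCondition",
    "spectral_response",
    "flow",
    "prior_precision_from_probability",
    "generate_observation",
]

N_STATES = 3  # (x_l, x_l', x_nu)
N_CAUSES = 2  # (v_l, v_nu)


@dataclass
class TuningBank:
    """Tonotopic bank of Gaussian tuning curves in log-frequency."""

    preferred_log_frequencies: np.ndarray
    tuning_width: float

    def __post_init__(self) -> None:
        self.preferred_log_frequencies = np.asarray(
            self.preferred_log_frequencies, dtype=float
        )
        if self.preferred_log_frequencies.shape != (50,):
            raise ValueError("the tonotopic bank has exactly 50 channels")
        if np.any(np.diff(self.preferred_log_frequencies) <= 0):
            raise ValueError("preferred log-frequencies must be strictly increasing")
        if self.tuning_width <= 0:
            raise ValueError("tuning width must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.preferred_log_frequencies)

    @classmethod
    def around(cls, standard_frequency: float, config: ModelConfig) -> "TuningBank":
        """Bank centred on the standard tone, spanning +/- span_widths tuning widths."""
        c = config.tuning
        half = c.span_widths * c.tuning_width
        nu = np.log(standard_frequency) + np.linspace(-half, half, c.n_channels)
        return cls(nu, c.tuning_width)


@dataclass
class OddballCondition:
    """One cell of an oddball design: what is played and how rare it is."""

    standard_frequency: float  # Hz
    deviance_magnitude: float  # proportional frequency shift, e.g. 0.127
    deviant_probability: float
    trial_type: Literal["standard", "deviant"] = "deviant"

    def __post_init__(self) -> None:
        if self.standard_frequency <= 0:
            raise ValueError("standard frequency must be positive")
        if self.deviance_magnitude < 0:
            raise ValueError("deviance magnitude must be nonnegative")
        if not 0 < self.deviant_probability < 1:
            raise ValueError("deviant probability must lie in (0, 1)")
        if self.trial_type not in ("standard", "deviant"):
            raise ValueError("trial_type must be 'standard' or 'deviant'")

    @property
    def deviant_frequency(self) -> float:
        return self.standard_frequency * (1.0 + self.deviance_magnitude)

    @property
    def presented_log_frequency(self) -> float:
        f = self.deviant_frequency if self.trial_type == "deviant" else self.standard_frequency
        return float(np.log(f))


def spectral_response(log_frequency: float, loudness: float, tuning: TuningBank) -> np.ndarray:
    """Activity of the 50 frequency channels for a tone at ``log_frequency``.

    Channel ``i`` responds with ``loudness * exp(-(nu - nu_i)^2 / (2 w^2))``:
    multiplicative loudness gain times a Gaussian tuning factor measuring how
    close the log-frequency is to the channel's preferred log-frequency.
    """
    if not (np.isfinite(log_frequency) and np.isfinite(loudness)):
        raise ValueError("non-finite input to spectral_response")
    z = (log_frequency - tuning.preferred_log_frequencies) / tuning.tuning_width
    return loudness * np.exp(-0.5 * z * z)


def prior_precision_from_probability(
    p: float, floor: float = 1.0, scale: float = 32.0
) -> float:
    """Prior precision on the target frequency implied by deviant probability.

    ``precision = floor + scale * (-ln p)``: the rarer the deviant, the more
    confidently the standard is predicted.  Strictly decreasing and continuous
    on (0, 1), unbounded as p -> 0, approaching ``floor`` as p -> 1.
    """
    if not 0 < p < 1:
        raise ValueError("deviant probability must lie strictly in (0, 1)")
    return floor + scale * (-np.log(p))


@dataclass
class AuditoryHDM:
    """The auditory generative model, parameterized for one trial.

    Doubles as the state-space interface consumed by the generalized filter
    (``f``, ``g``, their Jacobians, precisions, generalized prior mean).
    """

    tuning: TuningBank
    kappa_freq: float
    loudness_matrix: np.ndarray          # 2x2, decaying spiral
    loudness_drive: np.ndarray           # 2-vector multiplying v_l
    obs_log_precision: float
    state_log_precision: float
    cause_log_precisions: np.ndarray     # (v_l, v_nu)
    smoothness: float
    prior_mean_freq: float               # eta_nu, natural log Hz
    prior_precision_freq: float
    envelope_peak_time: float
    envelope_width: float
    envelope_amplitude: float

    def __post_init__(self) -> None:
        self.loudness_matrix = np.asarray(self.loudness_matrix, dtype=float)
        self.loudness_drive = np.asarray(self.loudness_drive, dtype=float)
        self.cause_log_precisions = np.asarray(self.cause_log_precisions, dtype=float)
        if self.kappa_freq <= 0:
            raise ValueError("kappa_freq must be positive")
        if self.prior_precision_freq <= 0:
            raise ValueError("prior precision must be positive")
        eig = np.linalg.eigvals(self.loudness_matrix)
        if np.any(eig.real >= 0) or np.all(np.abs(eig.imag) < 1e-12):
            raise ValueError(
                "loudness matrix must have complex eigenvalues with negative "
                f"real part (decaying spiral); got {eig}"
            )

    # -- construction -----------------------------------------------------

    @classmethod
    def _build(
        cls,
        config: ModelConfig,
        condition: OddballCondition,
        prior_mean_freq: float,
        generation_side: bool,
    ) -> "AuditoryHDM":
        d, n = config.dynamics, config.noise
        A = np.array([[0.0, 1.0], [-d.omega_loud**2, -2.0 * d.zeta_loud * d.omega_loud]])
        drive = np.array([0.0, d.omega_loud**2])
        if generation_side:
            obs_lp = state_lp = n.gen_log_precision
            cause_lp = np.array([n.gen_log_precision, n.gen_log_precision])
            prior_prec = 1.0  # cause_log_precisions already carry the full weight
        else:
            obs_lp, state_lp = n.obs_log_precision, n.state_log_precision
            cause_lp = np.array([n.loudness_cause_log_precision, 0.0])
            prior_prec = prior_precision_from_probability(
                condition.deviant_probability,
                config.prior.precision_floor,
                config.prior.precision_scale,
            )
        return cls(
            tuning=TuningBank.around(condition.standard_frequency, config),
            kappa_freq=d.kappa_freq,
            loudness_matrix=A,
            loudness_drive=drive,
            obs_log_precision=obs_lp,
            state_log_precision=state_lp,
            cause_log_precisions=cause_lp,
            smoothness=n.smoothness,
            prior_mean_freq=prior_mean_freq,
            prior_precision_freq=prior_prec,
            envelope_peak_time=config.envelope.peak_time,
            envelope_width=config.envelope.width,
            envelope_amplitude=config.envelope.amplitude,
        )

    @classmethod
    def for_generation(cls, config: ModelConfig, condition: OddballCondition) -> "AuditoryHDM":
        """Generation-side model: near-deterministic precisions, prior at the played tone."""
        return cls._build(config, condition, condition.presented_log_frequency, True)

    @classmethod
    def for_recognition(
        cls,
        config: ModelConfig,
        condition: OddballCondition,
        expected_frequency: float | None = None,
    ) -> "AuditoryHDM":
        """Listener's model: epistemic precisions, prior at the *expected* tone.

        ``expected_frequency`` defaults to the standard; the prior precision on
        the target frequency is set from the condition's deviant probability.
        """
        if expected_frequency is None:
            expected_frequency = condition.standard_frequency
        return cls._build(config, condition, float(np.log(expected_frequency)), False)

    # -- state-space interface --------------------------------------------

    @property
    def n_obs(self) -> int:
        return self.tuning.n_channels

    @property
    def n_states(self) -> int:
        return N_STATES

    @property
    def n_causes(self) -> int:
        return N_CAUSES

    def initial_state_mean(self) -> np.ndarray:
        """Belief at trial start: silence, frequency at the expected tone."""
        return np.array([0.0, 0.0, self.prior_mean_freq])

    def loudness_readout(self, x: np.ndarray) -> float:
        """l(x): the loudness entering the spectrogram.  Kept as its own
        function so alternative readouts (softplus, exponential) are one-line
        swaps."""
        return float(x[0])

    def g(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        return generate_observation(x, self)

    def g_jac(self, x: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nu_i = self.tuning.preferred_log_frequencies
        w = self.tuning.tuning_width
        z = (x[2] - nu_i) / w
        phi = np.exp(-0.5 * z * z)
        Gx = np.zeros((self.n_obs, N_STATES))
        Gx[:, 0] = phi                                   # d/dx_l
        Gx[:, 2] = self.loudness_readout(x) * phi * (nu_i - x[2]) / w**2  # d/dx_nu
        Gv = np.zeros((self.n_obs, N_CAUSES))
        return Gx, Gv

    def f(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        return flow(x, v, self)

    def f_jac(self, x: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Fx = np.zeros((N_STATES, N_STATES))
        Fx[:2, :2] = self.loudness_matrix
        Fx[2, 2] = -self.kappa_freq
        Fv = np.zeros((N_STATES, N_CAUSES))
        Fv[:2, 0] = self.loudness_drive
        Fv[2, 1] = self.kappa_freq
        return Fx, Fv

    def envelope(self, t: np.ndarray | float) -> np.ndarray | float:
        """Gaussian loudness bump v_l(t)."""
        z = (np.asarray(t, dtype=float) - self.envelope_peak_time) / self.envelope_width
        return self.envelope_amplitude * np.exp(-0.5 * z * z)

    def prior_mean_generalized(self, t: float, order: int) -> np.ndarray:
        """Generalized prior mean of the causes at time t: shape (order, 2).

        The loudness cause's prior mean is the Gaussian bump (with analytic
        derivatives); the target frequency's prior mean is constant.
        """
        out = np.zeros((order, N_CAUSES))
        b = float(self.envelope(t))
        u = (t - self.envelope_peak_time) / self.envelope_width**2
        out[0] = (b, self.prior_mean_freq)
        if order > 1:
            out[1, 0] = -u * b
        if order > 2:
            out[2, 0] = (u**2 - 1.0 / self.envelope_width**2) * b
        if order > 3:
            out[3, 0] = (3.0 * u / self.envelope_width**2 - u**3) * b
        return out

    def obs_precision(self) -> np.ndarray:
        return np.full(self.n_obs, np.exp(self.obs_log_precision))

    def state_precision(self) -> np.ndarray:
        return np.full(N_STATES, np.exp(self.state_log_precision))

    def cause_precision(self) -> np.ndarray:
        return np.array(
            [np.exp(self.cause_log_precisions[0]),
             np.exp(self.cause_log_precisions[1]) * self.prior_precision_freq]
        )


def flow(x: np.ndarray, v: np.ndarray, model: AuditoryHDM) -> np.ndarray:
    """dx/dt of the hidden states.

    The instantaneous log-frequency relaxes towards the target at rate kappa;
    the loudness pair follows a driven damped oscillation that spirals to
    zero when the drive is absent.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite input to flow")
    dx = np.empty(N_STATES)
    dx[:2] = model.loudness_matrix @ x[:2] + model.loudness_drive * v[0]
    dx[2] = model.kappa_freq * (v[1] - x[2])
    return dx


def generate_observation(x: np.ndarray, model: AuditoryHDM) -> np.ndarray:
    """Sensory prediction g(x): loudness readout times the tonotopic tuning."""
    x = np.asarray(x, dtype=float)
    return spectral_response(float(x[2]), model.loudness_readout(x), model.tuning)
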