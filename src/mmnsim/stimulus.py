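"""Stochastic stimulus generation.

Samples the hidden causes of one oddball trial (a target log-frequency and a
Gaussian loudness bump), integrates the auditory HDM forward with smooth
noise at generation-side precisions, and returns the resulting 50-channel
spectrogram together with the ground-truth hidden trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .config import ModelConfig
from .hdm import N_CAUSES, N_STATES, AuditoryHDM, OddballCondition, generate_observation

__all__ = [
    "Spectrogram",
    "NoiseSpec",
    "StimulusTruth",
    "sample_target_frequency",
    "loudness_cause",
    "smooth_noise",
    "generate_stimulus",
]


@dataclass
class Spectrogram:
    """Uniformly sampled 50-channel sensory input trajectory."""

    times: np.ndarray          # native time, uniform
    channels: np.ndarray       # (n_times, 50)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != 50:
            raise ValueError("spectrogram must have 50 channels")
        if len(self.times) != len(self.channels):
            raise ValueError("times and channels disagree in length")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("non-finite spectrogram entries")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class NoiseSpec:
    """One smooth noise stream: marginal precision and autocorrelation width."""

    log_precision: float
    smoothness: float

    def __post_init__(self) -> None:
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


@dataclass
class StimulusTruth:
    """Ground-truth trajectories behind a generated stimulus (diagnostics)."""

    target_log_frequency: float
    states: np.ndarray   # (n_times, 3)
    causes: np.ndarray   # (n_times, 2)


def sample_target_frequency(
    condition: OddballCondition, rng: np.random.Generator | int, sigma_draw: float = 0.002
) -> float:
    """Draw the trial's true target log-frequency.

    Normal around log(standard) for standard trials and around
    log(standard * (1 + deviance_magnitude)) for deviant trials, with a small
    trial-to-trial jitter ``sigma_draw`` (log-frequency units).
    """
    rng = np.random.default_rng(rng)
    return float(rng.normal(condition.presented_log_frequency, sigma_draw))


def loudness_cause(t: np.ndarray | float, model: AuditoryHDM) -> np.ndarray | float:
    """The loudness hidden cause v_l(t): a Gaussian bump.

    In native units it peaks at ``envelope_peak_time`` with SD
    ``envelope_width``; after the ERP time warp the peak falls at about 70 ms
    post stimulus onset with an SD of about 30 ms.
    """
    return model.envelope(t)


def smooth_noise(
    n_steps: int,
    dt: float,
    spec: NoiseSpec,
    rng: np.random.Generator | int,
    n_streams: int = 1,
) -> np.ndarray:
    """Stationary Gaussian noise with Gaussian autocorrelation, shape (n_steps, n_streams).

    White Gaussian noise is convolved with a Gaussian kernel and rescaled so
    the marginal variance is ``1 / precision`` and the autocorrelation falls
    to exp(-1/2) at a lag equal to ``spec.smoothness`` (kernel SD =
    smoothness / sqrt(2), since the autocorrelation of the filtered process
    is the kernel's self-convolution).
    """
    if n_steps < 2:
        raise ValueError("need at least two steps")
    rng = np.random.default_rng(rng)
    sigma_k = spec.smoothness / np.sqrt(2.0) / dt  # kernel SD in samples
    half = max(1, int(np.ceil(4.0 * sigma_k)))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_k) ** 2)
    k /= np.sqrt(np.sum(k * k))  # unit marginal variance after filtering
    pad = len(k)
    white = rng.standard_normal((n_steps + 2 * pad, n_streams))
    smooth = fftconvolve(white, k[:, None], mode="same", axes=0)[pad:-pad]
    return smooth * np.exp(-0.5 * spec.log_precision)


def generate_stimulus(
    condition: OddballCondition,
    config: ModelConfig,
    rng: np.random.Generator | int,
    model: AuditoryHDM | None = None,
) -> tuple[Spectrogram, StimulusTruth]:
    """Integrate the stochastic HDM forward for one trial.

    Returns the spectrogram the listener receives and the true hidden
    trajectories.  Same seed and condition give a bit-identical stimulus.
    """
    rng = np.random.default_rng(rng)
    if model is None:
        model = AuditoryHDM.for_generation(config, condition)
    grid = config.grid
    n, dt = grid.n_steps, grid.dt
    times = np.arange(n) * dt

    v_nu = sample_target_frequency(condition, rng, config.prior.sigma_draw)
    spec = NoiseSpec(config.noise.gen_log_precision, config.noise.smoothness)
    w_state = smooth_noise(n, dt, spec, rng, n_streams=N_STATES)
    z_obs = smooth_noise(n, dt, spec, rng, n_streams=model.n_obs)
    z_cause = smooth_noise(n, dt, spec, rng, n_streams=N_CAUSES)

    causes = np.column_stack(
        [np.asarray(model.envelope(times)), np.full(n, v_nu)]
    ) + z_cause
    states = np.empty((n, N_STATES))
    x = np.array([0.0, 0.0, v_nu])
    channels = np.empty((n, model.n_obs))
    for i in range(n):
        states[i] = x
        channels[i] = generate_observation(x, model) + z_obs[i]
        dx = model.f(x, causes[i]) + w_state[i]
        x = x + dt * dx
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"stimulus integration diverged at step {i} (t={times[i]:.4f})"
            )
    return (
        Spectrogram(times, channels),
        StimulusTruth(v_nu, states, causes),
    )
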