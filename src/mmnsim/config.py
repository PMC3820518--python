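"""Model configuration: every tunable constant, with documented defaults.

The configuration round-trips through YAML (or JSON, which YAML subsumes) so
that a whole simulation is reproducible from a single plain-text file.  Time
inside the simulator runs in dimensionless "native" units; the ERP forward
model maps native time to milliseconds (see :mod:`mmnsim.erp`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class TuningConfig:
    """Tonotopic bank of frequency-selective channels in primary auditory cortex."""

    n_channels: int = 50
    #: tuning-curve standard deviation, in natural-log-frequency units
    tuning_width: float = 0.15
    #: half-span of the preferred frequencies around the standard, in tuning widths
    span_widths: float = 4.0


@dataclass
class DynamicsConfig:
    """Hidden-state dynamics: frequency relaxation and the loudness oscillator."""

    #: rate at which instantaneous frequency converges to the target (1/native time)
    kappa_freq: float = 12.7
    #: natural frequency of the damped loudness oscillator (rad/native time)
    omega_loud: float = 8.0
    #: damping ratio of the loudness oscillator; < 1 gives the decaying spiral
    zeta_loud: float = 0.6


@dataclass
class EnvelopeConfig:
    """Gaussian loudness bump driving each trial (the hidden cause v_l)."""

    peak_time: float = 1.0      # native time of the bump maximum
    width: float = 0.3          # native-time standard deviation
    amplitude: float = 1.0      # peak loudness (arbitrary units)


@dataclass
class NoiseConfig:
    """Log-precisions of the smooth noise streams.

    Generation-side precisions are much higher than recognition-side ones:
    stimuli are produced almost deterministically while the listener allows
    for epistemic uncertainty about the generative process.
    """

    gen_log_precision: float = 16.0        # all generation-side streams
    obs_log_precision: float = 4.0         # recognition: sensory channels
    state_log_precision: float = 4.0       # recognition: motion of hidden states
    loudness_cause_log_precision: float = 2.0  # recognition: prior on v_l
    #: Gaussian autocorrelation width of every noise stream (native time)
    smoothness: float = 0.04


@dataclass
class PriorConfig:
    """Mapping from deviant probability to prior precision on the target frequency.

    precision(p) = floor + scale * (-ln p): monotone decreasing in p,
    unbounded as p -> 0, approaching ``floor`` as p -> 1.
    """

    precision_floor: float = 1.0
    precision_scale: float = 32.0
    #: SD of the per-trial draw of the true target log-frequency
    sigma_draw: float = 0.002


@dataclass
class GridConfig:
    """Native-time simulation grid: baseline, stimulus, post-stimulus decay."""

    n_steps: int = 256
    t_total: float = 4.0

    @property
    def dt(self) -> float:
        return self.t_total / self.n_steps


@dataclass
class FilterConfig:
    """Generalized-filtering settings."""

    embed_order_states: int = 4   # generalized orders for states and data
    embed_order_causes: int = 2   # generalized orders for causes
    #: rate constant of the gradient flow on precision-weighted error; < 1
    #: slows evidence accumulation without moving its fixed point
    gradient_rate: float = 0.15
    #: norm bound beyond which the belief trajectory is declared divergent
    divergence_norm: float = 1e6


@dataclass
class ObservationConfig:
    """Defaults for the ERP observation model (see :mod:`mmnsim.erp`)."""

    #: sigmoid gains per source: A1, Heschl's gyrus, IFG
    slopes: tuple[float, float, float] = (0.07, 0.05, 0.15)
    #: lead-field weights per source, in microvolts per unit LFP
    lead_field: tuple[float, float, float] = (-8.0, -4.0, -8.0)
    offset: float = 0.0           # constant scalp term, microvolts
    conduction_shift: float = 10.0  # ear-to-cortex delay, ms
    stimulus_duration_ms: float = 70.0  # warped stimulus duration (bump FWHM)


@dataclass
class ModelConfig:
    tuning: TuningConfig = field(default_factory=TuningConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    prior: PriorConfig = field(default_factory=PriorConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    observation: ObservationConfig = field(default_factory=ObservationConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            subcls = f.default_factory  # type: ignore[misc]
            if dataclasses.is_dataclass(subcls):
                pass
            subcls = {
                "tuning": TuningConfig, "dynamics": DynamicsConfig,
                "envelope": EnvelopeConfig, "noise": NoiseConfig,
                "prior": PriorConfig, "grid": GridConfig,
                "filter": FilterConfig, "observation": ObservationConfig,
            }[f.name]
            known = {x.name for x in dataclasses.fields(subcls)}
            extra = set(sub) - known
            if extra:
                raise KeyError(f"unknown keys in config section '{f.name}': {sorted(extra)}")
            sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
            kwargs[f.name] = subcls(**sub)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_listify(self.to_dict()), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _listify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
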