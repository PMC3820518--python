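"""Oddball simulation experiments.

Each condition runs two simulations on independently sampled stimuli of the
same tone B: one where the listener expected the standard A (deviant trial)
and one where B itself was expected (standard trial).  The MMN is the
deviant-minus-standard difference wave; the deviance-magnitude x
deviant-probability sweep tabulates its peak, amplitude and latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig
from .erp import (
    ERPWaveform,
    ObservationParams,
    ProcessedERP,
    baseline_correct,
    erp_from_errors,
)
from .gfilter import FilterResult, filter_run
from .hdm import AuditoryHDM, OddballCondition
from .metrics import NoMmnDetectedError, difference_wave, fractional_area_latency, mmn_amplitude
from .stimulus import StimulusTruth, generate_stimulus

__all__ = ["ConditionResult", "run_condition", "sweep", "summarize_contrasts",
           "DEFAULT_MAGNITUDES", "DEFAULT_PROBABILITIES"]

#: default sweep grids: the four magnitudes of the magnitude series plus the
#: 12.7% tone used for the probability series; probabilities 0.4 ... 0.05
DEFAULT_MAGNITUDES = (0.02, 0.04, 0.127, 0.27, 0.32)
DEFAULT_PROBABILITIES = (0.4, 0.3, 0.2, 0.1, 0.05)


@dataclass
class ConditionResult:
    condition: OddballCondition
    standard: ProcessedERP
    deviant: ProcessedERP
    mmn_filtered: ERPWaveform
    mmn_unfiltered: ERPWaveform
    latency_ms: float | None
    amplitude_uv: float | None
    peak_uv: float
    truth_deviant: StimulusTruth
    truth_standard: StimulusTruth
    filter_deviant: FilterResult
    filter_standard: FilterResult
    seed: int


def _process(result: FilterResult, params: ObservationParams) -> ProcessedERP:
    processed, _ = erp_from_errors(result.errors, params)
    return ProcessedERP(
        baseline_correct(processed.filtered),
        baseline_correct(processed.unfiltered),
    )


def run_condition(
    condition: OddballCondition,
    config: ModelConfig | None = None,
    obs_params: ObservationParams | None = None,
    rng_seed: int = 0,
) -> ConditionResult:
    """Simulate one oddball condition end to end.

    Both trials present the condition's tone B; the deviant trial expects the
    standard A, the standard trial expects B.  The prior precision on the
    target frequency follows the condition's deviant probability in both.
    """
    config = config or ModelConfig()
    obs_params = obs_params or ObservationParams.from_config(config)
    fc = config.filter
    ss = np.random.SeedSequence(rng_seed)
    seed_dev, seed_std = ss.spawn(2)

    presented = OddballCondition(
        condition.standard_frequency,
        condition.deviance_magnitude,
        condition.deviant_probability,
        trial_type="deviant",
    )
    try:
        stim_dev, truth_dev = generate_stimulus(presented, config, np.random.default_rng(seed_dev))
        model_dev = AuditoryHDM.for_recognition(config, presented)  # expects the standard
        res_dev = filter_run(stim_dev, model_dev, fc.embed_order_states,
                             fc.embed_order_causes, fc.divergence_norm,
                             fc.gradient_rate)

        stim_std, truth_std = generate_stimulus(presented, config, np.random.default_rng(seed_std))
        model_std = AuditoryHDM.for_recognition(
            config, presented, expected_frequency=presented.deviant_frequency
        )
        res_std = filter_run(stim_std, model_std, fc.embed_order_states,
                             fc.embed_order_causes, fc.divergence_norm,
                             fc.gradient_rate)
    except (FloatingPointError, RuntimeError) as exc:
        raise RuntimeError(
            f"condition (magnitude={condition.deviance_magnitude}, "
            f"p={condition.deviant_probability}, seed={rng_seed}) failed: {exc}"
        ) from exc

    erp_dev = _process(res_dev, obs_params)
    erp_std = _process(res_std, obs_params)
    mmn_filt = difference_wave(erp_dev.filtered, erp_std.filtered)
    mmn_unfilt = difference_wave(erp_dev.unfiltered, erp_std.unfiltered)
    peak = float(mmn_filt.voltages.min())
    try:
        latency = fractional_area_latency(mmn_unfilt)
        amplitude = mmn_amplitude(mmn_filt, latency)
    except (NoMmnDetectedError, ValueError):
        latency = amplitude = None
    return ConditionResult(
        condition=condition,
        standard=erp_std,
        deviant=erp_dev,
        mmn_filtered=mmn_filt,
        mmn_unfiltered=mmn_unfilt,
        latency_ms=latency,
        amplitude_uv=amplitude,
        peak_uv=peak,
        truth_deviant=truth_dev,
        truth_standard=truth_std,
        filter_deviant=res_dev,
        filter_standard=res_std,
        seed=rng_seed,
    )


def sweep(
    magnitudes: Sequence[float] = DEFAULT_MAGNITUDES,
    probabilities: Sequence[float] = DEFAULT_PROBABILITIES,
    config: ModelConfig | None = None,
    obs_params: ObservationParams | None = None,
    seeds: Sequence[int] = (0, 1, 2),
    standard_frequency: float = 1000.0,
) -> pd.DataFrame:
    """Cross-product sweep; one tidy row per condition x seed.

    Failures are recorded in the ``error`` column and the sweep continues.
    """
    if not len(magnitudes) or not len(probabilities):
        raise ValueError("magnitude and probability grids must be nonempty")
    rows = []
    for mag in magnitudes:
        for p in probabilities:
            for seed in seeds:
                row: dict = {
                    "magnitude": mag, "probability": p, "seed": seed,
                    "latency_ms": np.nan, "amplitude_uv": np.nan,
                    "peak_uv": np.nan, "error": "",
                }
                try:
                    cond = OddballCondition(standard_frequency, mag, p)
                    res = run_condition(cond, config, obs_params, seed)
                    row.update(
                        latency_ms=np.nan if res.latency_ms is None else res.latency_ms,
                        amplitude_uv=np.nan if res.amplitude_uv is None else res.amplitude_uv,
                        peak_uv=res.peak_uv,
                    )
                except Exception as exc:  # noqa: BLE001 - partial failures are data
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_contrasts(table: pd.DataFrame) -> dict:
    """The qualitative MMN phenomenology, evaluated on condition means.

    Returns a dict with the four classic contrasts plus the
    probability-by-magnitude interaction:

    - ``amplitude_increases_with_magnitude`` (at p = 0.05)
    - ``amplitude_increases_with_rarity`` (at magnitude 12.7%)
    - ``latency_shorter_at_large_magnitude`` (32% vs 12.7%, p = 0.05)
    - ``latency_insensitive_to_probability`` (latency spread over p at
      magnitudes <= 12.7% smaller than the magnitude-driven shift)
    - ``interaction_probability_effect_grows_with_magnitude``
    """
    ok = table[table["error"] == ""]
    means = ok.groupby(["magnitude", "probability"])[
        ["latency_ms", "amplitude_uv", "peak_uv"]
    ].mean()

    def depth(mag, p):
        return -means.loc[(mag, p), "peak_uv"]

    def lat(mag, p):
        return means.loc[(mag, p), "latency_ms"]

    mags = sorted(ok["magnitude"].unique())
    probs = sorted(ok["probability"].unique())
    out: dict = {}
    p_ref = min(probs)
    depths_mag = [depth(m, p_ref) for m in mags]
    out["amplitude_increases_with_magnitude"] = bool(
        np.all(np.diff(depths_mag) > 0)
    )
    mag_ref = 0.127 if 0.127 in mags else mags[len(mags) // 2]
    depths_p = [depth(mag_ref, p) for p in sorted(probs, reverse=True)]
    out["amplitude_increases_with_rarity"] = bool(np.all(np.diff(depths_p) > 0))
    big, mid = max(mags), mag_ref
    lat_shift = lat(mid, p_ref) - lat(big, p_ref)
    out["latency_shorter_at_large_magnitude"] = bool(lat_shift > 0)
    spread = max(
        float(np.ptp([lat(m, p) for p in probs]))
        for m in mags if m <= mag_ref
    )
    out["latency_insensitive_to_probability"] = bool(spread < lat_shift)
    p_hi, p_lo = max(probs), min(probs)
    m_lo = min(mags)
    inter_big = depth(big, p_lo) - depth(big, p_hi)
    inter_small = depth(m_lo, p_lo) - depth(m_lo, p_hi)
    out["interaction_probability_effect_grows_with_magnitude"] = bool(inter_big > inter_small)
    out["latency_shift_large_vs_mid_magnitude_ms"] = float(lat_shift)
    out["latency_spread_over_probability_ms"] = float(spread)
    return out
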