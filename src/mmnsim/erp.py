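"""Forward model from prediction errors to a single-electrode ERP.

Four stages mirror how real recordings arise and are processed:

1. time warp — the dimensionless simulation axis is shifted (conduction
   delay from the ear) and scaled so the stimulus lasts 70 ms;
2. sigmoid activation — each error unit's signed precision-weighted error
   passes through a logistic (firing cannot be negative and saturates),
   and units within a source sum into a local field potential (LFP);
3. lead field — the scalp potential is a linear combination of the three
   source LFPs (A1, Heschl's gyrus, IFG) plus a constant;
4. simulated data processing — resampling to 200 Hz and a 3rd-order
   Butterworth low-pass at 40 Hz.  Both the filtered and the unfiltered
   resampled waveforms are kept: latency estimation uses the unfiltered one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfilt, sosfilt_zi
from scipy.special import expit

from .config import ModelConfig
from .gfilter import ErrorTrajectory

__all__ = [
    "ObservationParams",
    "ERPWaveform",
    "ProcessedERP",
    "timewarp",
    "source_lfp",
    "scalp_potential",
    "postprocess",
    "baseline_correct",
    "erp_from_errors",
    "write_waveform",
    "read_waveform",
]

FWHM_PER_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ObservationParams:
    """Parameters of the error-to-ERP mapping.

    ``slopes`` are the sigmoid gains per source (A1, Heschl, IFG);
    ``lead_field`` the per-source scalp weights in microvolts; ``offset`` a
    constant scalp term.  ``time_scale`` converts native time to ms and
    ``conduction_shift`` (ms) places stimulus onset after the ear-to-cortex
    delay; ``native_onset`` is the native time of stimulus onset.
    """

    slopes: np.ndarray
    lead_field: np.ndarray
    offset: float = 0.0
    conduction_shift: float = 10.0
    time_scale: float = 1.0
    native_onset: float = 0.0

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.lead_field = np.asarray(self.lead_field, dtype=float)
        if self.slopes.shape != (3,) or self.lead_field.shape != (3,):
            raise ValueError("three sources: slopes and lead_field must have length 3")
        if np.any(self.slopes <= 0):
            raise ValueError("sigmoid slopes must be positive")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")

    @classmethod
    def from_config(cls, config: ModelConfig) -> "ObservationParams":
        o, e = config.observation, config.envelope
        native_fwhm = FWHM_PER_SD * e.width
        return cls(
            slopes=np.array(o.slopes),
            lead_field=np.array(o.lead_field),
            offset=o.offset,
            conduction_shift=o.conduction_shift,
            time_scale=o.stimulus_duration_ms / native_fwhm,
            native_onset=e.peak_time - 2.0 * e.width,
        )

    def warp_times(self, t_native: np.ndarray) -> np.ndarray:
        return (np.asarray(t_native, float) - self.native_onset) * self.time_scale \
            + self.conduction_shift


@dataclass
class ERPWaveform:
    """Uniformly sampled scalp potential."""

    times: np.ndarray       # ms, peristimulus
    voltages: np.ndarray    # microvolts
    sampling_rate: float    # Hz

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must align")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-7, atol=1e-9):
            raise ValueError("ERP waveform must be uniformly sampled")


@dataclass
class ProcessedERP:
    """Output of the simulated data processing stage."""

    filtered: ERPWaveform    # 200 Hz, low-passed at 40 Hz
    unfiltered: ERPWaveform  # 200 Hz, resampled only


def timewarp(errors: ErrorTrajectory, params: ObservationParams) -> ErrorTrajectory:
    """Affine map of the error time axis onto milliseconds; values unchanged."""
    return ErrorTrajectory(
        times=params.warp_times(errors.times),
        xi_sensory=errors.xi_sensory,
        xi_states=errors.xi_states,
        xi_causes=errors.xi_causes,
    )


def source_lfp(xi: np.ndarray, slope: float) -> np.ndarray:
    """Local field potential of one source: per-unit logistic, summed.

    Each error unit is a neuronal population whose field adds linearly;
    its activation ``1 / (1 + exp(-slope * xi))`` is nonnegative and
    saturates for large prediction errors.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    xi = np.atleast_2d(np.asarray(xi, dtype=float).T).T
    return expit(slope * xi).sum(axis=1)


def scalp_potential(
    lfps: tuple[np.ndarray, np.ndarray, np.ndarray],
    times_ms: np.ndarray,
    params: ObservationParams,
) -> ERPWaveform:
    """Linear lead-field superposition of the three source LFPs plus a constant."""
    lengths = {len(x) for x in lfps} | {len(times_ms)}
    if len(lengths) != 1:
        raise ValueError("LFP time axes are not aligned")
    v = params.offset + sum(w * lfp for w, lfp in zip(params.lead_field, lfps))
    dt_ms = float(times_ms[1] - times_ms[0])
    return ERPWaveform(np.asarray(times_ms, float), np.asarray(v, float), 1000.0 / dt_ms)


def postprocess(wave: ERPWaveform, target_rate: float = 200.0, cutoff: float = 40.0) -> ProcessedERP:
    """Resample to 200 Hz then 3rd-order Butterworth low-pass at 40 Hz (single pass)."""
    if wave.sampling_rate < 2 * cutoff or wave.sampling_rate < 2 * target_rate:
        raise ValueError(
            f"input rate {wave.sampling_rate:.0f} Hz too low for {target_rate:.0f} Hz "
            f"resampling with a {cutoff:.0f} Hz low-pass"
        )
    step = 1000.0 / target_rate
    t0 = np.ceil(wave.times[0] / step) * step
    t1 = np.floor(wave.times[-1] / step) * step
    grid = np.arange(t0, t1 + 0.5 * step, step)
    resampled = np.interp(grid, wave.times, wave.voltages)
    unfiltered = ERPWaveform(grid, resampled, target_rate)
    sos = butter(3, cutoff, btype="low", fs=target_rate, output="sos")
    # start from the DC steady state of the first sample
    zi = sosfilt_zi(sos) * resampled[0]
    filtered, _ = sosfilt(sos, resampled, zi=zi)
    return ProcessedERP(ERPWaveform(grid, filtered, target_rate), unfiltered)


def baseline_correct(wave: ERPWaveform, until_ms: float = 0.0) -> ERPWaveform:
    """Subtract the mean over the pre-stimulus interval (times < until_ms)."""
    mask = wave.times < until_ms
    if not np.any(mask):
        raise ValueError("no samples in the baseline interval")
    return replace(wave, voltages=wave.voltages - wave.voltages[mask].mean())


def erp_from_errors(
    errors: ErrorTrajectory, params: ObservationParams
) -> tuple[ProcessedERP, ERPWaveform]:
    """Full forward map: warp, sigmoid LFPs, lead field, data processing.

    Returns the processed (200 Hz) pair and the raw high-rate scalp waveform.
    """
    warped = timewarp(errors, params)
    lfps = (
        source_lfp(warped.xi_sensory, params.slopes[0]),
        source_lfp(warped.xi_states, params.slopes[1]),
        source_lfp(warped.xi_causes, params.slopes[2]),
    )
    raw = scalp_potential(lfps, warped.times, params)
    return postprocess(raw), raw


def write_waveform(path, wave: ERPWaveform) -> None:
    """Two-column delimited text: time_ms, voltage_uV."""
    np.savetxt(
        path,
        np.column_stack([wave.times, wave.voltages]),
        header="time_ms\tvoltage_uV",
        delimiter="\t",
        comments="",
    )


def read_waveform(path) -> ERPWaveform:
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("waveform files are two-column (time_ms, voltage_uV)")
    dt = data[1, 0] - data[0, 0]
    return ERPWaveform(data[:, 0], data[:, 1], 1000.0 / dt)
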