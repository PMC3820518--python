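"""MMN estimators: difference wave, fractional-area latency, windowed amplitude.

The MMN is the deviant-minus-standard difference wave.  Its latency is the
fractional-area estimate: within the window bounded by the first and last
half-amplitude crossings of the trough, the time splitting the (negative)
area into equal halves.  Its amplitude is the mean of the low-pass filtered
difference wave within +/-10 ms of that latency.  Latency is estimated on
the unfiltered waveform.
"""

from __future__ import annotations

import numpy as np

from .erp import ERPWaveform

__all__ = [
    "NoMmnDetectedError",
    "difference_wave",
    "fractional_area_latency",
    "mmn_amplitude",
    "trough_half_width",
]


class NoMmnDetectedError(ValueError):
    """The difference wave has no negative deflection to estimate."""


def difference_wave(deviant_erp: ERPWaveform, standard_erp: ERPWaveform) -> ERPWaveform:
    """Deviant ERP minus standard ERP, pointwise."""
    if deviant_erp.times.shape != standard_erp.times.shape or not np.allclose(
        deviant_erp.times, standard_erp.times
    ):
        raise ValueError("deviant and standard ERPs must share the time axis")
    return ERPWaveform(
        deviant_erp.times.copy(),
        deviant_erp.voltages - standard_erp.voltages,
        deviant_erp.sampling_rate,
    )


def _half_depth_window(wave: ERPWaveform, fraction_of_depth: float = 0.5) -> tuple[float, float, float]:
    """Trough depth and the first/last crossing times of ``fraction * depth``.

    Crossings are linearly interpolated between samples.
    """
    v = wave.voltages
    t = wave.times
    i_min = int(np.argmin(v))
    depth = v[i_min]
    if depth >= 0:
        raise NoMmnDetectedError("no negative deflection in the difference wave")
    half = fraction_of_depth * depth  # negative threshold
    below = v <= half
    if not below.any():
        raise NoMmnDetectedError("trough never reaches the half-amplitude level")
    first = int(np.argmax(below))
    last = len(v) - 1 - int(np.argmax(below[::-1]))
    # interpolate the crossings just outside the below-threshold run
    if first > 0:
        t_lo = t[first - 1] + (half - v[first - 1]) / (v[first] - v[first - 1]) * (
            t[first] - t[first - 1]
        )
    else:
        t_lo = t[0]
    if last < len(v) - 1:
        t_hi = t[last] + (half - v[last]) / (v[last + 1] - v[last]) * (
            t[last + 1] - t[last]
        )
    else:
        t_hi = t[-1]
    return float(depth), float(t_lo), float(t_hi)


def fractional_area_latency(wave: ERPWaveform, fraction: float = 0.5) -> float:
    """Time (ms) at which ``fraction`` of the trough's area lies to the left.

    The trough window runs from the first to the last half-depth crossing;
    area is the trapezoidal integral of the rectified-negative waveform
    inside it, and the split point is interpolated within the deciding
    segment, so the estimate is sub-sample accurate.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    _, t_lo, t_hi = _half_depth_window(wave)
    # dense, endpoint-exact grid over the window keeps the quadrature simple
    grid = np.union1d(
        wave.times[(wave.times >= t_lo) & (wave.times <= t_hi)], [t_lo, t_hi]
    )
    v = np.interp(grid, wave.times, wave.voltages)
    neg = np.minimum(v, 0.0)
    seg = 0.5 * (neg[1:] + neg[:-1]) * np.diff(grid)  # trapezoid, negative areas
    total = seg.sum()
    target = fraction * total
    # cum decreases from 0 towards total; locate the segment crossing target
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.nonzero(cum <= target)[0]
    k = max(int(idx[0]) - 1, 0) if len(idx) else len(seg) - 1
    frac = (target - cum[k]) / seg[k] if seg[k] != 0 else 0.0
    return float(grid[k] + frac * (grid[k + 1] - grid[k]))


def trough_half_width(wave: ERPWaveform) -> float:
    """Width (ms) of the trough at half its depth (first-to-last crossing)."""
    _, t_lo, t_hi = _half_depth_window(wave)
    return t_hi - t_lo


def mmn_amplitude(filtered_wave: ERPWaveform, latency: float, half_window_ms: float = 10.0) -> float:
    """Mean voltage of the filtered difference wave within +/-10 ms of the latency."""
    t = filtered_wave.times
    if latency - half_window_ms < t[0] or latency + half_window_ms > t[-1]:
        raise ValueError("amplitude window truncated by the trial edge")
    mask = (t >= latency - half_window_ms) & (t <= latency + half_window_ms)
    return float(filtered_wave.voltages[mask].mean())
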