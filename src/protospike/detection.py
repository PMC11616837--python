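"""Threshold-based spike detection on voltage traces.

The detector removes a slow baseline with a centered rolling median,
estimates the noise scale robustly (1.4826 x median absolute deviation, so
spikes do not inflate it), and accepts local maxima of the residual that
clear both an adaptive threshold (k x noise scale) and an absolute
amplitude floor, with a refractory rule that keeps the larger of two
conflicting peaks. Detection is deterministic for a fixed trace/config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import argrelextrema

from .core_io import SpikeTrain, VoltageTrace

__all__ = ["DetectionConfig", "detect_spikes", "interspike_intervals"]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for :func:`detect_spikes`.

    baseline_window : s — span of the centered rolling median.
    threshold_k : multiples of the robust noise scale a peak must exceed.
    min_amplitude : mV — absolute floor (0.3 mV sits just below the
        smallest amplitude reported for these systems, 0.38 mV).
    refractory : s — minimum separation between accepted spikes.
    """

    baseline_window: float = 600.0
    threshold_k: float = 5.0
    min_amplitude: float = 0.3
    refractory: float = 60.0

    def __post_init__(self) -> None:
        if min(self.baseline_window, self.threshold_k, self.min_amplitude,
               self.refractory) <= 0:
            raise ValueError("all detection parameters must be positive")


def detect_spikes(trace: VoltageTrace, config: DetectionConfig | None = None) -> SpikeTrain:
    """Extract spike times and baseline-subtracted amplitudes from a trace."""
    config = config or DetectionConfig()
    window_samples = int(round(config.baseline_window * trace.sampling_rate))
    if trace.times.size < window_samples:
        raise ValueError("trace shorter than the baseline window")
    window_samples = max(3, window_samples | 1)  # odd for a centered median

    residual = trace.values - median_filter(
        trace.values, size=window_samples, mode="nearest"
    )
    mad = np.median(np.abs(residual - np.median(residual)))
    noise_scale = 1.4826 * mad
    threshold = max(config.threshold_k * noise_scale, config.min_amplitude)

    peaks = argrelextrema(residual, np.greater_equal, order=1)[0]
    # greater_equal admits plateau runs; keep one sample per plateau
    if peaks.size:
        peaks = peaks[np.concatenate(([True], np.diff(peaks) > 1))]
    peaks = peaks[residual[peaks] >= threshold]

    # refractory pass: keep the larger amplitude on conflict
    accepted: list[int] = []
    refractory_samples = config.refractory * trace.sampling_rate
    for p in peaks:
        if accepted and p - accepted[-1] < refractory_samples:
            if residual[p] > residual[accepted[-1]]:
                accepted[-1] = p
        else:
            accepted.append(p)

    idx = np.asarray(accepted, dtype=int)
    return SpikeTrain(
        spike_times=trace.times[idx] - trace.times[0] if idx.size else np.empty(0),
        amplitudes=residual[idx] if idx.size else np.empty(0),
        duration=trace.duration,
    )


def interspike_intervals(train: SpikeTrain) -> np.ndarray:
    """First differences of the spike times (s); length n-1."""
    if train.n_spikes < 2:
        raise ValueError("need at least 2 spikes for ISIs")
    return np.diff(train.spike_times)
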