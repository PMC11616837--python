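"""Izhikevich neuron simulation and the input/output comparison battery.

The two-variable Izhikevich model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

reproduces a wide range of cortical firing patterns with four
dimensionless parameters. Here a regular-spiking neuron stands in for the
thalamocortical input signal; a configurable :class:`TransductionModel`
(gain, low-pass, soft saturation, offset, noise, optional anticipatory
delay) stands in for the signal transformation by the
proteinoid-chondroitin network — it is an explicit stand-in, not a fitted
mechanism. :func:`analyze_pair` assembles the comparison statistics:
descriptive blocks, Welch t, Pearson r, two-sample KS, and the
cross-correlation lag.

Lag sign convention: NEGATIVE lag means the output's pattern precedes the
input's (anticipation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core_io import SummaryStats
from .stats import summarize

__all__ = [
    "IzhikevichParams",
    "TransductionModel",
    "ThalamocorticalResult",
    "simulate_izhikevich",
    "transduce",
    "cross_correlation_lag",
    "welch_t",
    "ks_two_sample",
    "analyze_pair",
]

SPIKE_THRESHOLD_MV = 30.0


@dataclass(frozen=True)
class IzhikevichParams:
    """Model parameters; defaults are the canonical regular-spiking cell.

    ``current`` may be a scalar (tonic drive) or an array with one value
    per integration step.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v0: float = -65.0
    u0: float | None = None  # default b * v0
    dt: float = 1.0  # ms
    current: float | np.ndarray = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def simulate_izhikevich(
    params: IzhikevichParams, duration: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-Euler integration; returns (v, u, spike_times) in mV / ms.

    Whenever v crosses the 30 mV threshold the pre-reset sample is stored
    as 30 mV, a spike time is recorded, and the after-spike reset v <- c,
    u <- u + d is applied. Raises if the state diverges to non-finite
    values (naming the step).
    """
    if duration < params.dt:
        raise ValueError("duration must be at least one step")
    n = int(round(duration / params.dt))
    current = np.broadcast_to(np.asarray(params.current, dtype=float), (n,))
    dt = params.dt
    v = np.empty(n)
    u = np.empty(n)
    spikes = []
    vk = params.v0
    uk = params.b * params.v0 if params.u0 is None else params.u0
    for k in range(n):
        if not (math.isfinite(vk) and math.isfinite(uk)):
            raise FloatingPointError(f"state diverged at step {k} (t={k * dt} ms)")
        if vk >= SPIKE_THRESHOLD_MV:
            # pre-reset sample clamped to the threshold; the reset state is
            # stored at the next sample before integration resumes
            v[k] = SPIKE_THRESHOLD_MV
            u[k] = uk
            spikes.append(k * dt)
            vk = params.c
            uk = uk + params.d
            continue
        v[k] = vk
        u[k] = uk
        dv = 0.04 * vk * vk + 5.0 * vk + 140.0 - uk + current[k]
        du = params.a * (params.b * vk - uk)
        vk = vk + dt * dv
        uk = uk + dt * du
    return v, u, np.asarray(spikes)


@dataclass(frozen=True)
class TransductionModel:
    """Configurable stand-in for the proteinoid-chondroitin network.

    output = lowpass(gain * (input - input_rest)) -> soft saturation ->
    + offset + noise, optionally advanced by ``delay_ms`` so output
    patterns precede the input (negative cross-correlation lag). The
    network is taken to respond to deviations of the membrane potential
    from its resting level, not to the absolute potential. Defaults
    attenuate a ~20 mV-sd input to a ~0.3 mV-sd output around +1.5 mV
    with a 122 ms anticipatory lag, the scale of the reference
    thalamocortical comparison.
    """

    gain: float = 0.04
    lowpass_tau_ms: float = 5.0
    saturation_mv: float = 5.0
    offset_mv: float = 1.49
    noise_sd_mv: float = 0.05
    delay_ms: float = 122.0
    input_rest_mv: float = -65.0

    def __post_init__(self) -> None:
        if self.lowpass_tau_ms <= 0:
            raise ValueError("lowpass time constant must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise sd must be >= 0")
        if self.saturation_mv <= 0:
            raise ValueError("saturation level must be positive")


def transduce(
    signal, model: TransductionModel, seed=0, *, dt_ms: float = 1.0
) -> np.ndarray:
    """Apply the transduction stand-in to a signal; same length as input."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = dt_ms / (model.lowpass_tau_ms + dt_ms)
    drive = model.gain * (x - model.input_rest_mv)
    y = np.empty_like(x)
    acc = drive[0]
    for i, di in enumerate(drive):  # first-order IIR low-pass
        acc += alpha * (di - acc)
        y[i] = acc
    y = model.saturation_mv * np.tanh(y / model.saturation_mv)
    if model.delay_ms > 0:
        shift = int(round(model.delay_ms / dt_ms))
        if shift > 0:
            y = np.concatenate([y[shift:], np.full(shift, y[-1])])
    y = y + model.offset_mv
    if model.noise_sd_mv > 0:
        y = y + rng.normal(0.0, model.noise_sd_mv, size=y.size)
    return y


def cross_correlation_lag(x, y, max_lag: int) -> tuple[int, np.ndarray]:
    """Lag (samples, signed) maximizing the Pearson correlation of x_t, y_{t+l}.

    Returns ``(lag, correlations)`` where ``correlations[l + max_lag]`` is
    the correlation at lag l in [-max_lag, max_lag]. Negative lag means
    y's pattern precedes x's.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if x.size <= 2 * max_lag:
        raise ValueError("signals must be longer than 2 * max_lag")
    lags = np.arange(-max_lag, max_lag + 1)
    corrs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: x.size - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: y.size + lag]
        if a.std() == 0 or b.std() == 0:
            raise ValueError("zero-variance overlap at lag %d" % lag)
        corrs[i] = np.corrcoef(a, b)[0, 1]
    return int(lags[np.argmax(corrs)]), corrs


def welch_t(
    mean_x: float, sd_x: float, n_x: int, mean_y: float, sd_y: float, n_y: int
) -> float:
    """Unequal-variance (Welch) two-sample t statistic from summary stats."""
    if n_x < 2 or n_y < 2:
        raise ValueError("need n >= 2 per group")
    if sd_x < 0 or sd_y < 0 or (sd_x == 0 and sd_y == 0):
        raise ValueError("sds must be >= 0 and not both zero")
    return (mean_x - mean_y) / math.sqrt(sd_x**2 / n_x + sd_y**2 / n_y)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ThalamocorticalResult:
    """Comparison-statistics block for an input/output signal pair."""

    input_stats: SummaryStats  # mV
    output_stats: SummaryStats  # mV
    welch_t: float
    t_p_value: float
    pearson_r: float
    ks_statistic: float
    ks_p_value: float
    lag_at_max_corr_ms: float

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")
        if not 0 <= self.ks_statistic <= 1:
            raise ValueError("KS statistic must be in [0, 1]")


def analyze_pair(
    input_signal, output_signal, *, dt_ms: float = 1.0, max_lag_ms: float = 500.0
) -> ThalamocorticalResult:
    """Full comparison battery for equal-length input/output signals."""
    x = np.asarray(input_signal, dtype=float).ravel()
    y = np.asarray(output_signal, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    sx, sy = summarize(x), summarize(y)
    t = welch_t(sx.mean, sx.sd, sx.n, sy.mean, sy.sd, sy.n)
    # Welch-Satterthwaite df for the p-value
    vx, vy = sx.sd**2 / sx.n, sy.sd**2 / sy.n
    df = (vx + vy) ** 2 / (vx**2 / (sx.n - 1) + vy**2 / (sy.n - 1))
    t_p = 2.0 * sps.t.sf(abs(t), df)
    r = float(np.corrcoef(x, y)[0, 1])
    ks_d, ks_p = ks_two_sample(x, y)
    max_lag = int(round(max_lag_ms / dt_ms))
    lag, _ = cross_correlation_lag(x, y, max_lag)
    return ThalamocorticalResult(
        input_stats=sx,
        output_stats=sy,
        welch_t=t,
        t_p_value=float(t_p),
        pearson_r=r,
        ks_statistic=ks_d,
        ks_p_value=ks_p,
        lag_at_max_corr_ms=lag * dt_ms,
    )
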