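"""Fano-factor curves FF(w) for empirical trains and reference point processes.

The Fano factor Var(N)/E[N] of spike counts in windows of width w is 1 at
every w for a Poisson process, tends to the squared coefficient of
variation CV^2 of the ISI distribution as w grows for any renewal process,
and tends to 1 as w -> 0+ for any orderly process (counts become
Bernoulli). Empirical curves tile the recording with non-overlapping
windows (final partial window discarded); theoretical model curves are
Monte-Carlo estimates averaged over independent long realizations, with
the closed-form CV^2 large-window asymptote available for renewal
families.

A closed-form FF(w) expression sometimes quoted for renewal processes is
dimensionally inconsistent as printed in this system's source analysis and
fails the Poisson FF = 1 self-check, so the Monte-Carlo estimator is the
authoritative implementation here (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import SpikeTrain
from .stats import fano_factor
from .synthetic import PointProcessModel, generate_isis, isi_moments

__all__ = [
    "FanoCurve",
    "empirical_fano_curve",
    "theoretical_fano_curve",
    "ff_asymptote",
]


@dataclass(frozen=True)
class FanoCurve:
    """FF sampled on a window grid; NaN marks undefined (zero-count) points."""

    windows: np.ndarray  # s, strictly increasing
    ff: np.ndarray  # dimensionless; NaN where undefined
    n_windows_used: np.ndarray  # complete windows per grid point
    model_label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        if np.any(np.diff(w) <= 0):
            raise ValueError("windows must be strictly increasing")
        if np.any(self.ff[np.isfinite(self.ff)] < 0):
            raise ValueError("FF must be >= 0 where defined")


def log_window_grid(w_min: float, w_max: float, n_points: int = 30) -> np.ndarray:
    """Log-spaced window grid, default 30 points."""
    if w_min <= 0 or w_max <= w_min or n_points < 2:
        raise ValueError("need 0 < w_min < w_max and n_points >= 2")
    return np.geomspace(w_min, w_max, n_points)


def empirical_fano_curve(
    train: SpikeTrain,
    w_min: float,
    w_max: float,
    n_points: int = 30,
    *,
    model_label: str = "empirical",
) -> FanoCurve:
    """FF(w) of one spike train on a log-spaced window grid.

    Requires w_max <= duration / 2 so every grid point has at least two
    complete windows. Undefined points (zero mean count) are flagged as
    NaN rather than dropped.
    """
    if w_max > train.duration / 2:
        raise ValueError("w_max must be <= duration / 2")
    windows = log_window_grid(w_min, w_max, n_points)
    ff = np.empty(n_points)
    used = np.empty(n_points, dtype=int)
    for i, w in enumerate(windows):
        used[i] = int(train.duration // w)
        val = fano_factor(train, w)
        ff[i] = np.nan if val is None else val
    return FanoCurve(windows=windows, ff=ff, n_windows_used=used,
                     model_label=model_label)


def theoretical_fano_curve(
    model: PointProcessModel,
    windows,
    n_reps: int = 8,
    seed=0,
    *,
    isis_per_rep: int = 20_000,
) -> FanoCurve:
    """Monte-Carlo FF(w) of a point-process model.

    Simulates ``n_reps`` independent realizations of ``isis_per_rep``
    intervals each and averages the empirical FF per window across
    realizations.
    """
    windows = np.asarray(windows, dtype=float)
    rng = np.random.default_rng(seed)
    ff_acc = np.zeros(windows.size)
    ff_cnt = np.zeros(windows.size, dtype=int)
    used = np.zeros(windows.size, dtype=int)
    for _ in range(n_reps):
        isis = generate_isis(model, isis_per_rep, rng)
        times = np.cumsum(isis)
        duration = float(times[-1])
        train = SpikeTrain(
            spike_times=times[:-1], amplitudes=np.ones(times.size - 1),
            duration=duration,
        )
        for i, w in enumerate(windows):
            if duration // w < 2:
                continue
            val = fano_factor(train, w)
            if val is not None:
                ff_acc[i] += val
                ff_cnt[i] += 1
                used[i] += int(duration // w)
    ff = np.where(ff_cnt > 0, ff_acc / np.maximum(ff_cnt, 1), np.nan)
    return FanoCurve(windows=windows, ff=ff, n_windows_used=used,
                     model_label=model.family)


def ff_asymptote(model: PointProcessModel) -> float:
    """Closed-form large-window FF limit for renewal families: CV^2 of the ISI.

    gamma_renewal -> 1/shape; inverse_gaussian -> mean/shape; periodic -> 0;
    exponential_refractory -> (1/rate)^2 / (refractory + 1/rate)^2.
    Rate-switching families (MPP/APP) have no renewal CV^2 limit; use
    :func:`theoretical_fano_curve`.
    """
    if not model.is_renewal:
        raise ValueError(
            f"{model.family} is not a renewal family; use Monte-Carlo"
        )
    mean, var = isi_moments(model)
    return var / mean**2
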