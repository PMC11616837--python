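"""Descriptive and model-based statistics of spike amplitudes and periods.

Implements the statistics battery used to characterise microsphere spiking:
plugin skewness/kurtosis, the quartile/peak-to-peak/RMS summary block,
gamma density and maximum-likelihood fitting, Gaussian KDE with the Scott
bandwidth, firing rate, and the fixed-window Fano factor.

Estimator conventions
---------------------
* skewness = m3 / m2^(3/2), kurtosis = m4 / m2^2 with population (n
  denominator) central moments; a normal sample has kurtosis ~ 3. These are
  the plugin (method-of-moments) estimators, not the bias-corrected
  variants.
* sd uses the n-1 denominator; quartiles use linear interpolation
  (the "inclusive" scheme, numpy's default).
* The gamma fit stores a *scale* parameter b with mean = shape * b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .core_io import GammaFit, SpikeTrain, SummaryStats

__all__ = [
    "KDEstimate",
    "summarize",
    "skewness",
    "kurtosis",
    "gamma_pdf",
    "fit_gamma_mle",
    "scott_bandwidth",
    "kde",
    "firing_rate",
    "fano_factor",
    "cv_isi",
]


def _as1d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty input")
    if np.any(~np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    return arr


def skewness(values) -> float:
    """Plugin skewness m3 / m2^(3/2).

    Requires n >= 2 and nonzero variance.
    """
    x = _as1d(values)
    if x.size < 2:
        raise ValueError("skewness needs n >= 2")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero variance")
    return float(np.mean(d**3) / m2**1.5)


def kurtosis(values) -> float:
    """Plugin (non-excess) kurtosis m4 / m2^2; a normal sample gives ~3."""
    x = _as1d(values)
    if x.size < 2:
        raise ValueError("kurtosis needs n >= 2")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero variance")
    return float(np.mean(d**4) / m2**2)


def summarize(values) -> SummaryStats:
    """Descriptive block: mean/median/quartiles/min/max/sd/p2p/RMS/shape.

    For a single observation, sd, skewness and kurtosis are reported as 0
    with ``degenerate=True``; the same flag is set when the sample has zero
    variance.
    """
    x = _as1d(values)
    n = x.size
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    mn, mx = float(x.min()), float(x.max())
    degenerate = n < 2 or mx == mn
    return SummaryStats(
        n=n,
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=mn,
        max=mx,
        sd=0.0 if n < 2 else float(x.std(ddof=1)),
        peak_to_peak=mx - mn,
        rms=float(np.sqrt(np.mean(x**2))),
        skewness=0.0 if degenerate else skewness(x),
        kurtosis=0.0 if degenerate else kurtosis(x),
        degenerate=degenerate,
    )


def gamma_pdf(x, shape: float, scale: float):
    """Gamma density f(x) = x^(a-1) exp(-x/b) / (Gamma(a) b^a) for x > 0."""
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gamma density is defined for x > 0")
    log_pdf = (
        (shape - 1) * np.log(x)
        - x / scale
        - special.gammaln(shape)
        - shape * math.log(scale)
    )
    out = np.exp(log_pdf)
    return float(out) if out.ndim == 0 else out


def _gamma_loglik(x: np.ndarray, shape: float, scale: float) -> float:
    return float(
        np.sum(
            (shape - 1) * np.log(x)
            - x / scale
            - special.gammaln(shape)
            - shape * math.log(scale)
        )
    )


def fit_gamma_mle(
    values, *, tol: float = 1e-10, max_iter: int = 100
) -> GammaFit:
    """Maximum-likelihood gamma fit via Newton iteration on the profile score.

    The profile likelihood in the shape a satisfies
    ``log(a) - psi(a) = log(mean(x)) - mean(log x)``; Newton iteration
    starts from the method-of-moments estimate and the scale is recovered
    as ``mean(x) / a_hat`` (the MLE first-moment identity). Requires
    n >= 10 strictly positive observations.
    """
    x = _as1d(values)
    if x.size < 10:
        raise ValueError("gamma MLE needs n >= 10")
    if np.any(x <= 0):
        raise ValueError("gamma MLE needs strictly positive data")
    mean = float(x.mean())
    s = math.log(mean) - float(np.mean(np.log(x)))
    if s <= 0:
        raise ValueError("degenerate sample: log-mean inequality violated")
    var = float(x.var(ddof=1))
    a = mean**2 / var if var > 0 else 1.0  # method-of-moments start
    converged = False
    for _ in range(max_iter):
        f = math.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:  # fall back to bisection toward 0
            a_new = a / 2.0
        if abs(a_new - a) / a < tol:
            a = a_new
            converged = True
            break
        a = a_new
    scale = mean / a
    return GammaFit(
        shape=a,
        scale=scale,
        log_likelihood=_gamma_loglik(x, a, scale),
        n=x.size,
        converged=converged,
    )


def scott_bandwidth(values) -> float:
    """Scott's rule bandwidth h = n^(-1/5) * 1.06 * min(sd, IQR/1.34)."""
    x = _as1d(values)
    if x.size < 2:
        raise ValueError("bandwidth needs n >= 2")
    sd = float(x.std(ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate sample: zero spread")
    return x.size ** (-0.2) * 1.06 * spread


@dataclass(frozen=True)
class KDEstimate:
    """Gaussian kernel density estimate on an explicit grid."""

    grid: np.ndarray  # ordered evaluation points, data units
    density: np.ndarray  # >= 0, units 1/data-units
    bandwidth: float  # data units
    n: int  # sample size

    def integral(self) -> float:
        """Trapezoid integral of the density over the grid."""
        return float(np.trapezoid(self.density, self.grid))


def kde(values, bandwidth: float, grid) -> KDEstimate:
    """Gaussian-kernel density estimate at the given grid points."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = _as1d(values)
    g = np.asarray(grid, dtype=float).ravel()
    if g.size == 0:
        raise ValueError("empty grid")
    if g.size > 1 and np.any(np.diff(g) <= 0):
        raise ValueError("grid must be strictly increasing")
    z = (g[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (
        x.size * bandwidth * math.sqrt(2 * math.pi)
    )
    return KDEstimate(grid=g, density=dens, bandwidth=float(bandwidth), n=x.size)


def firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate: spike count divided by recording duration (spikes/s)."""
    if train.duration <= 0:
        raise ValueError("duration must be positive")
    return train.n_spikes / train.duration


def cv_isi(train: SpikeTrain) -> float:
    """Coefficient of variation of the interspike intervals (sd/mean, n-1 sd)."""
    if train.n_spikes < 3:
        raise ValueError("CV of ISIs needs at least 3 spikes")
    isis = np.diff(train.spike_times)
    return float(isis.std(ddof=1) / isis.mean())


def fano_factor(train: SpikeTrain, window: float) -> float | None:
    """Fano factor Var(N)/E[N] of counts in non-overlapping windows.

    The recording is tiled with consecutive windows of length ``window``
    starting at t=0; a final partial window is discarded. Variance uses the
    n-1 denominator. Returns ``None`` (undefined) when the mean count is
    zero; requires at least two complete windows.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_windows = int(train.duration // window)
    if n_windows < 2:
        raise ValueError("need at least 2 complete windows")
    edges = np.arange(n_windows + 1) * window
    counts, _ = np.histogram(train.spike_times, bins=edges)
    mean = counts.mean()
    if mean == 0:
        return None
    return float(counts.var(ddof=1) / mean)
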