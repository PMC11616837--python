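"""Domain types and file IO for proteinoid voltage-trace analysis.

The pipeline's in-memory currency is a small set of frozen dataclasses:
:class:`VoltageTrace` (uniformly sampled potential), :class:`SpikeTrain`
(spike times + amplitudes), :class:`SummaryStats` (descriptive block),
:class:`GammaFit` and :class:`AnalysisReport`. Traces travel as two-column
CSV with the unit declared in the header (``time_s,potential_mV`` or
``time_s,potential_V``); reports and spike trains travel as JSON.

All potentials are held internally in mV; volt-denominated inputs are
converted on read.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VoltageTrace",
    "SpikeTrain",
    "SummaryStats",
    "GammaFit",
    "AnalysisReport",
    "read_trace",
    "write_trace",
    "read_spike_train",
    "write_spike_train",
    "write_report",
    "read_report",
]

_STEP_RTOL = 1e-9


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled electrode potential time series.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing with a uniform step
        (relative tolerance 1e-9).
    values : array of float
        Potential at each sample, in mV.
    condition : str
        Condition label, e.g. ``"1.86"`` or ``"water"``.
    cs_concentration : float
        Chondroitin sulfate concentration in mg/ml (0 for water control).
    temperature_c : float or None
        Bath temperature in degrees Celsius, if recorded.
    """

    times: np.ndarray
    values: np.ndarray
    condition: str = ""
    cs_concentration: float = 0.0
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > _STEP_RTOL * max(abs(step), 1.0)):
            raise ValueError("non-uniform sampling: time step varies")

    @property
    def step(self) -> float:
        """Sampling interval in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def sampling_rate(self) -> float:
        """Samples per second (Hz)."""
        return 1.0 / self.step

    @property
    def duration(self) -> float:
        """Span from first to last sample plus one step, in seconds."""
        return float(self.times[-1] - self.times[0]) + self.step


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times with per-spike amplitudes over a known duration."""

    spike_times: np.ndarray  # s, strictly increasing, within [0, duration]
    amplitudes: np.ndarray  # mV, positive, same length
    duration: float  # s

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "spike_times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.ndim != 1 or a.ndim != 1 or t.size != a.size:
            raise ValueError("spike_times and amplitudes must be 1-D and equal length")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError("spike_times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("spike_times must lie within [0, duration]")
            if np.any(a <= 0):
                raise ValueError("amplitudes must be positive")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics block for amplitudes, periods or raw potential.

    ``sd`` uses the n-1 denominator; skewness and kurtosis use the
    population-moment plugin estimators (kurtosis of a normal is 3).
    For n = 1, sd/skewness/kurtosis are reported as 0 and ``degenerate``
    is set.
    """

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    sd: float
    peak_to_peak: float
    rms: float
    skewness: float
    kurtosis: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("quartile ordering violated")


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit.

    ``scale`` is the scale parameter b (mean = shape * scale). Reference
    analyses of this system print b under the name "rate parameter", but
    their own printed mean is shape*b, so b is a scale; see docs/methods.md.
    """

    shape: float
    scale: float
    log_likelihood: float
    n: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale


@dataclass(frozen=True)
class AnalysisReport:
    """Per-condition spike-train analysis: descriptive + model-based stats."""

    condition: str
    n_spikes: int
    duration: float  # s
    amplitude_stats: SummaryStats | None
    isi_stats: SummaryStats | None
    amplitude_fit: GammaFit | None
    firing_rate: float  # spikes/s
    cv_isi: float | None
    fano: float | None
    fano_window: float | None = None  # s


# ---------------------------------------------------------------------------
# trace CSV IO


def read_trace(
    path: str | Path,
    *,
    condition: str = "",
    cs_concentration: float = 0.0,
) -> VoltageTrace:
    """Read a two-column time/potential CSV into a :class:`VoltageTrace`.

    The header declares the unit: ``time_s,potential_mV`` or
    ``time_s,potential_V`` (volts are converted to mV). A headerless
    two-numeric-column file is accepted and assumed to be in mV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = path.open().readline()
    has_header = any(c.isalpha() for c in first.split(",")[0])
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError("expected two columns (time, potential)")
    scale = 1.0
    if has_header:
        unit_col = str(df.columns[1]).strip().lower()
        if unit_col.endswith("_v") or unit_col == "potential_v":
            scale = 1000.0
        elif not unit_col.endswith("_mv"):
            raise ValueError(
                f"potential column {df.columns[1]!r} must declare _mV or _V"
            )
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.any(~np.isfinite(times)) or np.any(~np.isfinite(values)):
        raise ValueError("non-numeric rows in trace file")
    return VoltageTrace(
        times=times,
        values=values * scale,
        condition=condition,
        cs_concentration=cs_concentration,
    )


def write_trace(trace: VoltageTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,potential_mV`` CSV (full float precision)."""
    df = pd.DataFrame({"time_s": trace.times, "potential_mV": trace.values})
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# spike-train JSON IO


def write_spike_train(train: SpikeTrain, path: str | Path) -> None:
    payload = {
        "spike_times_s": train.spike_times.tolist(),
        "amplitudes_mV": train.amplitudes.tolist(),
        "duration_s": train.duration,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_spike_train(path: str | Path) -> SpikeTrain:
    payload = json.loads(Path(path).read_text())
    return SpikeTrain(
        spike_times=np.asarray(payload["spike_times_s"], dtype=float),
        amplitudes=np.asarray(payload["amplitudes_mV"], dtype=float),
        duration=float(payload["duration_s"]),
    )


# ---------------------------------------------------------------------------
# analysis-report JSON IO


def _validate_finite(obj, context: str) -> None:
    if isinstance(obj, float) and not math.isfinite(obj):
        raise ValueError(f"non-finite value in report field {context}")
    if dataclasses.is_dataclass(obj):
        for f in dataclasses.fields(obj):
            _validate_finite(getattr(obj, f.name), f"{context}.{f.name}")


def _stats_to_dict(s: SummaryStats | None) -> dict | None:
    return None if s is None else dataclasses.asdict(s)


def write_report(report: AnalysisReport, path: str | Path) -> None:
    """Serialize a validated report to JSON with unit-annotated keys.

    Raises ``ValueError`` if any numeric field is NaN or infinite.
    """
    _validate_finite(report, "report")
    payload = {
        "condition": report.condition,
        "n_spikes": report.n_spikes,
        "duration_s": report.duration,
        "amplitude_stats_mV": _stats_to_dict(report.amplitude_stats),
        "isi_stats_s": _stats_to_dict(report.isi_stats),
        "amplitude_fit": (
            None
            if report.amplitude_fit is None
            else dataclasses.asdict(report.amplitude_fit)
        ),
        "firing_rate_spikes_per_s": report.firing_rate,
        "cv_isi": report.cv_isi,
        "fano": report.fano,
        "fano_window_s": report.fano_window,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_report(path: str | Path) -> AnalysisReport:
    p = json.loads(Path(path).read_text())

    def stats(d):
        return None if d is None else SummaryStats(**d)

    fit = p["amplitude_fit"]
    return AnalysisReport(
        condition=p["condition"],
        n_spikes=p["n_spikes"],
        duration=p["duration_s"],
        amplitude_stats=stats(p["amplitude_stats_mV"]),
        isi_stats=stats(p["isi_stats_s"]),
        amplitude_fit=None if fit is None else GammaFit(**fit),
        firing_rate=p["firing_rate_spikes_per_s"],
        cv_isi=p["cv_isi"],
        fano=p["fano"],
        fano_window=p["fano_window_s"],
    )
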