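"""High-level analysis: spike train -> full per-condition report."""

from __future__ import annotations

import numpy as np

from . import stats as st
from .core_io import AnalysisReport, SpikeTrain
from .detection import interspike_intervals

__all__ = ["analyze_train"]


def analyze_train(
    train: SpikeTrain,
    *,
    condition: str = "",
    fano_window: float | None = None,
    fit_amplitudes: bool = True,
) -> AnalysisReport:
    """Descriptive + model-based statistics for one spike train.

    ``fano_window`` defaults to 10x the mean ISI (clamped so at least two
    complete windows fit). Gamma fitting of amplitudes is skipped for
    trains with fewer than 10 spikes.
    """
    n = train.n_spikes
    amp_stats = st.summarize(train.amplitudes) if n >= 1 else None
    isi_stats = None
    cv = None
    fano = None
    window = None
    if n >= 2:
        isis = interspike_intervals(train)
        isi_stats = st.summarize(isis)
        if n >= 3:
            cv = st.cv_isi(train)
        window = fano_window if fano_window is not None else 10.0 * float(
            np.mean(isis)
        )
        window = min(window, train.duration / 2.0)
        fano = st.fano_factor(train, window)
    fit = None
    if fit_amplitudes and n >= 10:
        fit = st.fit_gamma_mle(train.amplitudes)
    return AnalysisReport(
        condition=condition,
        n_spikes=n,
        duration=train.duration,
        amplitude_stats=amp_stats,
        isi_stats=isi_stats,
        amplitude_fit=fit,
        firing_rate=st.firing_rate(train),
        cv_isi=cv,
        fano=fano,
        fano_window=window,
    )
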