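"""Threshold-crossing spike detection on extracellular voltage traces.

The trace is band-pass filtered (300–3000 Hz), the noise level is
estimated robustly as ``σ_n = median(|x|)/0.6745``, and events are
negative crossings below ``−k·σ_n`` with a 1 ms refractory lockout.
Amplitude is trough-to-peak over the standard 2.5 ms waveform window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator

from neuropheno.synth.mea import WAVEFORM_WINDOW_MS


class SpikeDetector(BaseEstimator):
    """Negative-threshold spike detector.

    Parameters
    ----------
    k : threshold multiplier on the robust noise SD (default 5).
    f_low, f_high : band-pass corner frequencies in Hz.
    refractory_ms : lockout after each detected trough.
    window_ms : waveform window length (trough at one third).

    Attributes (after :meth:`fit`)
    ------------------------------
    sigma_ : per-electrode robust noise SD of the filtered trace.
    """

    def __init__(
        self,
        k: float = 5.0,
        f_low: float = 300.0,
        f_high: float = 3000.0,
        refractory_ms: float = 1.0,
        window_ms: float = WAVEFORM_WINDOW_MS,
    ) -> None:
        self.k = k
        self.f_low = f_low
        self.f_high = f_high
        self.refractory_ms = refractory_ms
        self.window_ms = window_ms

    def _bandpass(self, traces: np.ndarray, fs: float) -> np.ndarray:
        sos = signal.butter(
            4, [self.f_low, self.f_high], btype="bandpass", fs=fs, output="sos"
        )
        return signal.sosfiltfilt(sos, traces, axis=-1)

    def fit(self, traces: np.ndarray, sampling_rate: float):
        if sampling_rate < 10000:
            raise ValueError("spike detection requires sampling_rate >= 10 kHz")
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        n_window = int(round(self.window_ms * 1e-3 * sampling_rate))
        if traces.shape[-1] < n_window:
            raise ValueError("trace shorter than one waveform window")
        self.sampling_rate_ = sampling_rate
        self.filtered_ = self._bandpass(traces, sampling_rate)
        self.sigma_ = np.median(np.abs(self.filtered_), axis=-1) / 0.6745
        return self

    def transform(self, traces: np.ndarray | None = None) -> pd.DataFrame:
        """Detect spikes on the fitted traces; returns a SpikeTable.

        Columns: electrode, time_s, amplitude_uv; per-event waveforms in
        ``.attrs['waveforms']``.
        """
        if traces is not None:
            self.fit(traces, self.sampling_rate_)
        fs = self.sampling_rate_
        n_window = int(round(self.window_ms * 1e-3 * fs))
        trough_off = n_window // 3
        lockout = int(round(self.refractory_ms * 1e-3 * fs))

        rows, wfs = [], []
        for el, (x, sigma) in enumerate(zip(self.filtered_, self.sigma_)):
            thr = -self.k * sigma
            below = x < thr
            # entry points of sub-threshold excursions
            entries = np.flatnonzero(below & ~np.roll(below, 1))
            if below.size and below[0]:
                entries = np.unique(np.concatenate([[0], entries]))
            last = -np.inf
            for e in entries:
                if e - last < lockout:
                    continue
                seg_end = min(e + lockout, x.size)
                trough = e + int(np.argmin(x[e:seg_end]))
                start = trough - trough_off
                if start < 0 or start + n_window > x.size:
                    continue  # no full waveform window (also guards filter edges)
                wf = x[start : start + n_window].copy()
                rows.append(
                    {
                        "electrode": el,
                        "time_s": trough / fs,
                        "amplitude_uv": wf.max() - wf.min(),
                    }
                )
                wfs.append(wf)
                last = trough

        table = pd.DataFrame(rows, columns=["electrode", "time_s", "amplitude_uv"])
        table.attrs["waveforms"] = (
            np.asarray(wfs) if wfs else np.empty((0, n_window))
        )
        table.attrs["sampling_rate"] = fs
        return table

    def fit_transform(self, traces: np.ndarray, sampling_rate: float) -> pd.DataFrame:
        return self.fit(traces, sampling_rate).transform()


def detect_spikes(
    trace: np.ndarray, sampling_rate: float, k: float = 5.0, **kwargs
) -> pd.DataFrame:
    """Detect spikes on one or more voltage traces (thin wrapper)."""
    return SpikeDetector(k=k, **kwargs).fit_transform(trace, sampling_rate)
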