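"""Max-Interval burst detection.

A burst opens when an inter-spike interval drops to ``isi_start`` or
below, extends while ISIs stay at or below ``isi_end``, and closes
otherwise. Bursts closer than ``min_ibi`` are merged, then bursts with
fewer than ``min_spikes`` spikes or shorter than ``min_duration`` are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

BURST_COLUMNS = ["start_s", "end_s", "n_spikes"]


@dataclass(frozen=True)
class MaxIntervalParams:
    isi_start: float = 0.17  # s, ISI that opens a burst
    isi_end: float = 0.3  # s, ISI that keeps a burst open
    min_ibi: float = 0.2  # s, bursts closer than this merge
    min_spikes: int = 3
    min_duration: float = 0.01  # s


class MaxIntervalBurstDetector(BaseEstimator):
    """Detect bursts in a single sorted spike train."""

    def __init__(
        self,
        isi_start: float = 0.17,
        isi_end: float = 0.3,
        min_ibi: float = 0.2,
        min_spikes: int = 3,
        min_duration: float = 0.01,
    ) -> None:
        self.isi_start = isi_start
        self.isi_end = isi_end
        self.min_ibi = min_ibi
        self.min_spikes = min_spikes
        self.min_duration = min_duration

    def transform(self, times: np.ndarray) -> pd.DataFrame:
        """Return a BurstSet DataFrame (start_s, end_s, n_spikes)."""
        t = np.asarray(times, dtype=float)
        if t.ndim != 1:
            raise ValueError("expected a 1-D spike-time array")
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be sorted")
        if t.size < 2:
            return pd.DataFrame(columns=BURST_COLUMNS).astype(
                {"start_s": float, "end_s": float, "n_spikes": int}
            )

        isi = np.diff(t)
        raw: list[list[int]] = []  # [first_idx, last_idx]
        i = 0
        while i < isi.size:
            if isi[i] <= self.isi_start:
                j = i + 1
                while j < isi.size and isi[j] <= self.isi_end:
                    j += 1
                raw.append([i, j])  # spikes i..j inclusive
                i = j + 1
            else:
                i += 1

        # merge bursts separated by < min_ibi
        merged: list[list[int]] = []
        for b in raw:
            if merged and t[b[0]] - t[merged[-1][1]] < self.min_ibi:
                merged[-1][1] = b[1]
            else:
                merged.append(b)

        rows = [
            (t[a], t[b], b - a + 1)
            for a, b in merged
            if (b - a + 1) >= self.min_spikes and (t[b] - t[a]) >= self.min_duration
        ]
        return pd.DataFrame(rows, columns=BURST_COLUMNS)

    def fit(self, times: np.ndarray, y=None):
        self.bursts_ = self.transform(times)
        return self


def detect_bursts(
    times: np.ndarray, params: MaxIntervalParams | None = None
) -> pd.DataFrame:
    """Max-Interval burst detection on one spike train (thin wrapper)."""
    p = params or MaxIntervalParams()
    return MaxIntervalBurstDetector(
        isi_start=p.isi_start,
        isi_end=p.isi_end,
        min_ibi=p.min_ibi,
        min_spikes=p.min_spikes,
        min_duration=p.min_duration,
    ).transform(times)
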