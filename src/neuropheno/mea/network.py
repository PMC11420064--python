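"""Single-unit and network metrics: firing/burst statistics, percentage
of spikes outside bursts, array-wide spike detection rate (ASDR),
autocorrelograms and burst-period estimation.

Conventions: time in seconds with recording start at 0; histogram bins
half-open ``[t, t + bin)``; autocorrelogram bins centered on integer
multiples of the bin width so the histogram is symmetric about lag 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from neuropheno.mea.bursts import MaxIntervalParams, detect_bursts


def spike_burst_stats(
    table: pd.DataFrame,
    duration: float,
    burst_params: MaxIntervalParams | None = None,
) -> pd.DataFrame:
    """Per-unit firing-rate, amplitude and burst statistics.

    ``table`` must carry electrode/unit/time_s (amplitude_uv optional).
    Burst statistics are NaN (not zero) for units without bursts.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rows = []
    for (el, u), sub in table.groupby(["electrode", "unit"]):
        t = np.sort(sub["time_s"].to_numpy())
        bursts = detect_bursts(t, burst_params)
        row = {
            "electrode": el,
            "unit": u,
            "n_spikes": t.size,
            "firing_rate_hz": t.size / duration,
            "mean_amplitude_uv": (
                sub["amplitude_uv"].mean() if "amplitude_uv" in sub else np.nan
            ),
            "n_bursts": len(bursts),
            "mean_burst_duration_s": np.nan,
            "mean_spikes_per_burst": np.nan,
            "pct_outside_bursts": pct_outside_bursts(t, bursts),
        }
        if len(bursts):
            row["mean_burst_duration_s"] = float(
                (bursts["end_s"] - bursts["start_s"]).mean()
            )
            row["mean_spikes_per_burst"] = float(bursts["n_spikes"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def pct_outside_bursts(times: np.ndarray, bursts: pd.DataFrame) -> float:
    """Percentage of spikes not inside any burst interval.

    Returns NaN for an empty train; 100 when no bursts were detected.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return float("nan")
    if len(bursts) == 0:
        return 100.0
    inside = np.zeros(t.size, dtype=bool)
    for start, end in zip(bursts["start_s"], bursts["end_s"]):
        inside |= (t >= start) & (t <= end)
    return 100.0 * (1.0 - inside.sum() / t.size)


def asdr(
    tables: pd.DataFrame | list[np.ndarray],
    duration: float,
    bin_s: float = 1.0,
) -> np.ndarray:
    """Array-wide spike detection rate: spikes per bin summed over units.

    ``tables`` is either a SpikeTable DataFrame or a list of spike-time
    arrays. The series sums to the total spike count.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    if isinstance(tables, pd.DataFrame):
        all_times = tables["time_s"].to_numpy()
    else:
        all_times = (
            np.concatenate([np.asarray(t, dtype=float) for t in tables])
            if tables
            else np.empty(0)
        )
    edges = np.arange(0.0, duration + bin_s, bin_s)
    counts, _ = np.histogram(all_times, bins=edges)
    return counts


def autocorrelogram(
    times: np.ndarray,
    bin_s: float = 0.1,
    max_lag: float = 15.0,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike-train autocorrelogram.

    Counts ordered spike-pair lags in ``(-max_lag, max_lag)`` (self-pairs
    at lag 0 excluded) into bins centered at integer multiples of
    ``bin_s``. Returns ``(lags, counts)``; normalized to peak 1 when
    requested. Fewer than 2 spikes yields an all-zero histogram.
    """
    t = np.sort(np.asarray(times, dtype=float))
    # keep only bins fully inside (-max_lag, max_lag): a half-covered edge
    # bin would show up as a spurious dip
    n_side = int(np.floor(max_lag / bin_s - 0.5))
    lags = np.arange(-n_side, n_side + 1) * bin_s
    counts = np.zeros(lags.size)
    if t.size < 2:
        return lags, counts

    edge = (n_side + 0.5) * bin_s
    pos = np.zeros(n_side + 1)  # bin 0 .. n_side for lags >= 0
    hi = np.searchsorted(t, t + edge, side="left")
    for i in range(t.size):
        d = t[i + 1 : hi[i]] - t[i]
        idx = np.minimum(np.floor(d / bin_s + 0.5).astype(int), n_side)
        np.add.at(pos, idx, 1.0)
    counts[n_side:] = pos
    counts[: n_side + 1] = pos[::-1]  # mirror: ordered pairs are symmetric
    counts[n_side] = 2.0 * pos[0]  # near-zero lags counted in both orders

    if normalize and counts.max() > 0:
        counts = counts / counts.max()
    return lags, counts


def mean_autocorrelogram(
    trains: list[np.ndarray],
    bin_s: float = 0.1,
    max_lag: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Average of per-unit peak-normalized autocorrelograms."""
    acgs = []
    lags = None
    for t in trains:
        lags, c = autocorrelogram(t, bin_s=bin_s, max_lag=max_lag, normalize=True)
        acgs.append(c)
    if lags is None:
        raise ValueError("no trains supplied")
    return lags, np.mean(acgs, axis=0)


def estimate_period(
    lags: np.ndarray,
    acg: np.ndarray,
    min_lag: float = 1.0,
    smooth_bins: int = 5,
    min_prominence: float = 0.1,
) -> float | None:
    """Burst-period estimate from a normalized mean autocorrelogram.

    The ACG is smoothed with a moving average and the lag of the highest
    local maximum beyond ``min_lag`` is returned; ``None`` when no peak
    reaches ``min_prominence``.
    """
    acg = np.asarray(acg, dtype=float)
    kernel = np.ones(smooth_bins)
    # edge-aware moving average: normalize by the in-range window size so
    # the array ends do not droop and fake peak prominence
    smooth = np.convolve(acg, kernel, mode="same") / np.convolve(
        np.ones_like(acg), kernel, mode="same"
    )
    side = (lags > min_lag)
    peaks, props = find_peaks(smooth, prominence=min_prominence)
    peaks = peaks[side[peaks]]
    if peaks.size == 0:
        return None
    best = peaks[np.argmax(smooth[peaks])]
    return float(lags[best])


def acg_flatness(lags: np.ndarray, acg: np.ndarray, min_lag: float = 0.3) -> float:
    """Max/median ratio of the ACG beyond ``|lag| > min_lag``.

    ~1 for a Poisson (flat) train, ≫1 for periodic network bursting.
    """
    tail = acg[np.abs(lags) > min_lag]
    med = np.median(tail)
    if med <= 0:
        return float("inf") if tail.max() > 0 else 1.0
    return float(tail.max() / med)
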