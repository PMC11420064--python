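"""Calcium-imaging quantification: ΔF/F, transient detection at >k·σ
above the noise level, rise (t1) and recovery (t2) kinetics, and
event-frequency summaries.

The same detector serves glutamate-sensor (iGluSnFr-style) event
counting: each active spot's trace is a ROI.

Pipeline
--------
1. ``dff``: baseline F0 is a running 20th percentile over a 30 s window;
   ΔF/F = (F − F0)/F0.
2. ``TransientDetector``: the noise SD σ is estimated as
   1.4826·MAD(diff(ΔF/F))/√2 (first differences cancel the transients,
   √2 rescales the difference of two iid samples). The series is
   median-centered and lightly smoothed (moving average, 0.25 s) before
   thresholding; a transient is a maximal contiguous excursion above
   0.5·σ whose peak exceeds k·σ. Onset is the last upward 0.5·σ
   crossing before the peak (refined on the unsmoothed series); the
   return is the first frame after the peak back below 0.5·σ for a
   sustained hold period — censored when the trace ends first.
   t1 = peak − onset, t2 = return − peak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter
from sklearn.base import BaseEstimator

TRANSIENT_COLUMNS = [
    "roi",
    "onset_s",
    "peak_s",
    "return_s",
    "amplitude",
    "t1_s",
    "t2_s",
    "censored",
]


def dff(
    F: np.ndarray,
    frame_rate: float,
    window_s: float = 30.0,
    percentile: float = 20.0,
) -> np.ndarray:
    """ΔF/F with a running-percentile baseline.

    Accepts a single trace or a (rois × frames) array. Raises when the
    estimated baseline is not strictly positive.
    """
    F = np.asarray(F, dtype=float)
    size = max(int(round(window_s * frame_rate)), 1)
    if size % 2 == 0:
        size += 1
    f0 = percentile_filter(F, percentile, size=(size,) if F.ndim == 1 else (1, size),
                           mode="nearest")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; ΔF/F undefined")
    return (F - f0) / f0


def _noise_sigma(x: np.ndarray) -> float:
    d = np.diff(x)
    return 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)


def _close_short_gaps(above: np.ndarray, min_gap: int) -> np.ndarray:
    """Fill interior below-threshold runs shorter than ``min_gap``."""
    out = above.copy()
    starts = np.flatnonzero(~above & np.roll(above, 1))
    for s in starts:
        if s == 0:
            continue
        e = s
        while e < out.size and not above[e]:
            e += 1
        if e < out.size and (e - s) < min_gap:
            out[s:e] = True
    return out


class TransientDetector(BaseEstimator):
    """Detect fluorescence transients exceeding ``k``·σ above the noise.

    Parameters
    ----------
    k : peak threshold in noise SDs (default 2, the standard criterion).
    cross_frac : onset/return sub-threshold level as a fraction of σ.
    smooth_s : moving-average window applied before thresholding.
    hold_s : a return to baseline must be sustained this long — shorter
        sub-threshold dips are treated as noise within the transient.
    sigma_floor : absolute lower bound on σ (ΔF/F units); keeps the
        thresholds finite on noiseless traces.
    """

    def __init__(
        self,
        k: float = 2.0,
        cross_frac: float = 0.5,
        smooth_s: float = 0.25,
        hold_s: float = 0.5,
        sigma_floor: float = 0.02,
    ) -> None:
        self.k = k
        self.cross_frac = cross_frac
        self.smooth_s = smooth_s
        self.hold_s = hold_s
        self.sigma_floor = sigma_floor

    def transform(self, dff_series: np.ndarray, frame_rate: float) -> pd.DataFrame:
        """Detect transients; returns a TransientSet DataFrame.

        ``dff_series`` may be 1-D (one ROI) or 2-D (rois × frames).
        """
        x = np.asarray(dff_series, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        rows = []
        for roi, series in enumerate(x):
            rows.extend(self._detect_one(series, frame_rate, roi))
        out = pd.DataFrame(rows, columns=TRANSIENT_COLUMNS)
        out.attrs["frame_rate"] = frame_rate
        return out

    def _detect_one(self, x: np.ndarray, fs: float, roi: int) -> list[dict]:
        raw_sigma = _noise_sigma(x)
        if raw_sigma == 0 and np.ptp(x) == 0:
            return []
        sigma = max(raw_sigma, self.sigma_floor)

        n_smooth = max(int(round(self.smooth_s * fs)), 1)
        if n_smooth > 1:
            kernel = np.ones(n_smooth) / n_smooth
            y = np.convolve(x, kernel, mode="same")
        else:
            y = x.copy()
        center = np.median(y)
        y = y - center
        x_c = x - center  # unsmoothed series for onset refinement

        low, high = self.cross_frac * sigma, self.k * sigma
        hold = max(int(round(self.hold_s * fs)), 1)
        above = _close_short_gaps(y > low, hold)

        starts = np.flatnonzero(above & ~np.roll(above, 1))
        if above.size and above[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        ends = np.flatnonzero(~above & np.roll(above, 1))  # first frame below

        events = []
        for s in starts:
            e_candidates = ends[ends > s]
            e = int(e_candidates[0]) if e_candidates.size else y.size
            censored = e == y.size
            seg = y[s:e]
            peak_rel = int(np.argmax(seg))
            if seg[peak_rel] <= high:
                continue
            peak = s + peak_rel
            # onset: last upward crossing of the sub-threshold level before
            # the peak, located on the unsmoothed series (the smoothing
            # window would otherwise pull the crossing early)
            below_raw = np.flatnonzero(x_c[s : peak + 1] <= low)
            onset = s + below_raw[-1] + 1 if below_raw.size else s
            onset = min(onset, peak)
            onset_t = onset / fs
            peak_t = peak / fs
            return_t = e / fs if not censored else (y.size - 1) / fs
            events.append(
                {
                    "roi": roi,
                    "onset_s": onset_t,
                    "peak_s": peak_t,
                    "return_s": return_t,
                    "amplitude": float(seg[peak_rel]),
                    "t1_s": peak_t - onset_t,
                    "t2_s": np.nan if censored else return_t - peak_t,
                    "censored": censored,
                }
            )
        return events

    def fit(self, dff_series: np.ndarray, frame_rate: float):
        self.transients_ = self.transform(dff_series, frame_rate)
        return self


def detect_transients(
    dff_series: np.ndarray, frame_rate: float, k: float = 2.0, **kwargs
) -> pd.DataFrame:
    """Detect transients on ΔF/F series (thin wrapper)."""
    return TransientDetector(k=k, **kwargs).transform(dff_series, frame_rate)


def kinetics(transients: pd.DataFrame) -> pd.DataFrame:
    """Per-transient rise (t1) and recovery (t2) times in seconds.

    Censored transients (trace ended before the return crossing) carry
    ``t2_s = NaN`` and are excluded from any mean.
    """
    return transients[["roi", "t1_s", "t2_s", "censored"]].copy()


def transient_frequency(
    transients: pd.DataFrame, duration: float, n_rois: int | None = None
) -> pd.DataFrame:
    """Events/min per ROI plus an active-cell flag (≥1 transient).

    ``n_rois`` includes silent ROIs in the output; defaults to the ROIs
    present in ``transients``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    counts = transients.groupby("roi").size()
    rois = range(n_rois) if n_rois is not None else counts.index
    n = pd.Series(0, index=pd.Index(rois, name="roi"), dtype=int)
    n.loc[counts.index] = counts
    out = pd.DataFrame(
        {
            "n_transients": n,
            "events_per_min": 60.0 * n / duration,
            "active": n > 0,
        }
    )
    return out.reset_index()
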