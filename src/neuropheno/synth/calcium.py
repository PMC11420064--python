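"""Simulated somatic calcium-imaging traces.

Each ROI trace is ``baseline + drift·t + baseline·Σ transients + noise``
where a transient is a difference of exponentials
``a·(exp(-t/τ_decay) - exp(-t/τ_rise))`` rescaled so its peak equals the
configured ΔF/F amplitude. Transient onsets follow a hard-core renewal
process: exponential inter-event gaps plus a dead time, so the mean rate
equals ``transient_rate`` exactly while adjacent events stay resolvable
(calcium recovery imposes a comparable refractory period in real cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CalciumSimConfig:
    n_rois: int = 30
    duration: float = 120.0  # s
    frame_rate: float = 20.0  # Hz
    transient_rate: float = 2.0  # events/min per ROI
    rise_tau: float = 0.2  # s
    decay_tau: float = 2.0  # s
    amplitude: float = 1.0  # ΔF/F
    baseline: float = 100.0  # a.u.
    drift_slope: float = 0.05  # a.u./s
    noise_sd: float = 2.0  # a.u. on F
    min_separation: float = 12.0  # s dead time between onsets
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rise_tau < self.decay_tau:
            raise ValueError("rise_tau must be smaller than decay_tau")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.transient_rate > 0:
            mean_gap = 60.0 / self.transient_rate
            if mean_gap <= self.min_separation:
                raise ValueError(
                    "transient_rate too high for min_separation dead time"
                )


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak.

    Peak occurs at ``t* = τr·τd/(τd−τr)·ln(τd/τr)``.
    """
    t = np.asarray(t, dtype=float)
    raw = np.where(
        t >= 0, np.exp(-t / decay_tau) - np.exp(-np.clip(t, 0, None) / rise_tau), 0.0
    )
    return raw / kernel_peak_value(rise_tau, decay_tau)


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    return rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)


def kernel_peak_value(rise_tau: float, decay_tau: float) -> float:
    tp = kernel_peak_time(rise_tau, decay_tau)
    return np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)


def _onsets(cfg: CalciumSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.transient_rate <= 0:
        return np.empty(0)
    exp_mean = 60.0 / cfg.transient_rate - cfg.min_separation
    times, t = [], 0.0
    while True:
        t += cfg.min_separation + rng.exponential(exp_mean)
        if t >= cfg.duration:
            break
        times.append(t)
    return np.asarray(times)


def gen_calcium(config: CalciumSimConfig):
    """Simulate fluorescence traces.

    Returns ``(traces DataFrame [roi x frame fluorescence], ground_truth)``.
    ``traces.attrs['frame_rate']`` carries the acquisition rate. Ground
    truth holds one row per planted transient: roi, onset_s, peak_s
    (onset + analytic peak time) and amplitude (ΔF/F).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration * cfg.frame_rate))
    t = np.arange(n_frames) / cfg.frame_rate
    tp = kernel_peak_time(cfg.rise_tau, cfg.decay_tau)

    traces = np.empty((cfg.n_rois, n_frames))
    events = []
    for roi in range(cfg.n_rois):
        f = cfg.baseline + cfg.drift_slope * t
        for onset in _onsets(cfg, rng):
            f = f + cfg.baseline * cfg.amplitude * transient_kernel(
                t - onset, cfg.rise_tau, cfg.decay_tau
            )
            events.append(
                {
                    "roi": roi,
                    "onset_s": onset,
                    "peak_s": onset + tp,
                    "amplitude": cfg.amplitude,
                }
            )
        if cfg.noise_sd > 0:
            f = f + rng.normal(0.0, cfg.noise_sd, size=n_frames)
        traces[roi] = f

    df = pd.DataFrame(traces, index=pd.RangeIndex(cfg.n_rois, name="roi"))
    df.attrs["frame_rate"] = cfg.frame_rate
    truth = pd.DataFrame(events, columns=["roi", "onset_s", "peak_s", "amplitude"])
    return df, {"transients": truth, "config": cfg}
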