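"""Simulated multi-electrode-array recordings.

Units fire as homogeneous Poisson processes on top of which array-wide
population bursts (jittered periodic windows during which every unit
elevates to ``in_burst_rate``) are superimposed. Each unit carries a
biphasic extracellular waveform template (negative trough followed by a
positive rebound); spike-table mode attaches one noisy template instance
per spike, raw mode renders the voltage traces at ``sampling_rate`` with
template collisions resolved by summation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: waveform window length used everywhere (detection, sorting, simulation)
WAVEFORM_WINDOW_MS = 2.5

# Default template bank: amplitudes span the tens-of-µV range typical of
# planar MEA recordings; widths differ so clusters separate in shape as
# well as in amplitude.
_DEFAULT_TEMPLATES = [
    (40.0, 0.4, 0.3),
    (80.0, 0.5, 0.35),
    (160.0, 0.6, 0.25),
    (60.0, 0.35, 0.45),
    (110.0, 0.55, 0.2),
    (200.0, 0.45, 0.3),
]


@dataclass(frozen=True)
class WaveformTemplate:
    """Biphasic extracellular spike template.

    Parameters
    ----------
    amplitude_uv : trough depth in µV (positive number).
    width_ms : Gaussian width (SD) of the negative lobe.
    biphasic_ratio : rebound amplitude as a fraction of the trough depth.
    """

    amplitude_uv: float
    width_ms: float = 0.5
    biphasic_ratio: float = 0.3

    def render(self, sampling_rate: float) -> np.ndarray:
        """Sample the template over the standard 2.5 ms window."""
        n = int(round(WAVEFORM_WINDOW_MS * 1e-3 * sampling_rate))
        t = (np.arange(n) - n // 3) / sampling_rate * 1e3  # ms, trough at 1/3
        w = self.width_ms
        trough = -self.amplitude_uv * np.exp(-0.5 * (t / w) ** 2)
        rebound = (
            self.biphasic_ratio
            * self.amplitude_uv
            * np.exp(-0.5 * ((t - 2.0 * w) / (1.6 * w)) ** 2)
        )
        return trough + rebound


@dataclass
class MEASimConfig:
    n_electrodes: int = 8
    units_per_electrode: int = 3
    duration: float = 300.0  # s
    templates: list[WaveformTemplate] | None = None
    background_rate: float = 0.5  # Hz per unit
    burst_period: float = 9.0  # s; 0 disables population bursting
    burst_jitter: float = 0.3  # s (SD of window-start jitter)
    burst_duration: float = 1.0  # s
    in_burst_rate: float = 15.0  # Hz per unit inside a burst window
    noise_sd: float = 3.0  # µV per sample
    sampling_rate: float = 20000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.burst_period and self.burst_period <= self.burst_duration:
            raise ValueError("burst_period must exceed burst_duration")
        if self.templates is None:
            self.templates = [
                WaveformTemplate(*_DEFAULT_TEMPLATES[i % len(_DEFAULT_TEMPLATES)])
                for i in range(self.units_per_electrode)
            ]

    def validate_for_raw(self) -> None:
        if self.sampling_rate < 10000:
            raise ValueError("raw traces require sampling_rate >= 10 kHz")


def _burst_windows(cfg: MEASimConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered periodic population-burst windows, shape (n, 2)."""
    if not cfg.burst_period:
        return np.empty((0, 2))
    starts = np.arange(cfg.burst_period / 2, cfg.duration - cfg.burst_duration, cfg.burst_period)
    starts = starts + rng.normal(0.0, cfg.burst_jitter, size=starts.size)
    starts = np.clip(starts, 0.0, cfg.duration - cfg.burst_duration)
    return np.column_stack([starts, starts + cfg.burst_duration])


def _unit_spike_times(
    cfg: MEASimConfig, windows: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n_bg = rng.poisson(cfg.background_rate * cfg.duration)
    times = [rng.uniform(0.0, cfg.duration, size=n_bg)]
    extra = max(cfg.in_burst_rate - cfg.background_rate, 0.0)
    for start, end in windows:
        n_in = rng.poisson(extra * (end - start))
        times.append(rng.uniform(start, end, size=n_in))
    return np.sort(np.concatenate(times))


def gen_mea(config: MEASimConfig, raw: bool = False):
    """Simulate an MEA recording.

    Returns ``(SpikeTable DataFrame, ground_truth)`` by default, or
    ``(Recording dict, ground_truth)`` when ``raw=True`` (keys
    ``voltage`` [electrode x sample, µV] and ``sampling_rate``).

    Ground truth keys: ``spikes`` (DataFrame electrode/unit/time_s),
    ``burst_windows``, ``templates``, ``config``.
    """
    rng = np.random.default_rng(config.seed)
    windows = _burst_windows(config, rng)

    recs = []
    for el in range(config.n_electrodes):
        for u in range(config.units_per_electrode):
            t = _unit_spike_times(config, windows, rng)
            recs.append(
                pd.DataFrame({"electrode": el, "unit": u, "time_s": t})
            )
    truth_spikes = (
        pd.concat(recs, ignore_index=True)
        .sort_values(["electrode", "unit", "time_s"], kind="stable")
        .reset_index(drop=True)
    )
    ground_truth = {
        "spikes": truth_spikes,
        "burst_windows": windows,
        "templates": list(config.templates),
        "config": config,
    }

    if raw:
        config.validate_for_raw()
        return _render_raw(config, truth_spikes, rng), ground_truth

    return _render_spike_table(config, truth_spikes, rng), ground_truth


def _render_spike_table(
    cfg: MEASimConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach noisy waveform instances and measured amplitudes."""
    templates = {i: t.render(cfg.sampling_rate) for i, t in enumerate(cfg.templates)}
    n_samp = len(next(iter(templates.values())))
    wf = np.empty((len(truth), n_samp))
    for u, tmpl in templates.items():
        idx = np.flatnonzero(truth["unit"].to_numpy() == u)
        wf[idx] = tmpl + rng.normal(0.0, cfg.noise_sd, size=(idx.size, n_samp))
    amplitude = wf.max(axis=1) - wf.min(axis=1)
    table = truth[["electrode", "unit", "time_s"]].copy()
    table["amplitude_uv"] = amplitude
    table.attrs["waveforms"] = wf
    table.attrs["sampling_rate"] = cfg.sampling_rate
    return table


def _render_raw(cfg: MEASimConfig, truth: pd.DataFrame, rng: np.random.Generator) -> dict:
    n_samples = int(round(cfg.duration * cfg.sampling_rate))
    voltage = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_electrodes, n_samples))
    templates = {i: t.render(cfg.sampling_rate) for i, t in enumerate(cfg.templates)}
    n_w = len(next(iter(templates.values())))
    trough_off = n_w // 3

    n_collisions = 0
    by_el = truth.groupby("electrode")
    for el, sub in by_el:
        samp = np.round(sub["time_s"].to_numpy() * cfg.sampling_rate).astype(int)
        order = np.argsort(samp)
        samp_sorted = samp[order]
        if samp_sorted.size > 1:
            n_collisions += int(np.sum(np.diff(samp_sorted) < n_w))
        for s, u in zip(samp, sub["unit"].to_numpy()):
            start = s - trough_off
            lo, hi = max(start, 0), min(start + n_w, n_samples)
            if hi <= lo:
                continue
            voltage[el, lo:hi] += templates[u][lo - start : hi - start]

    if len(truth) and n_collisions / len(truth) > 0.20:
        msg = (
            f"template collision rate {n_collisions / len(truth):.1%} exceeds 20% "
            "of spikes; detection recall will degrade"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    return {"voltage": voltage, "sampling_rate": cfg.sampling_rate}
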