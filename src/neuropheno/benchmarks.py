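"""End-to-end recovery benchmarks on seeded synthetic data.

Each function simulates data with planted ground truth, runs the
corresponding pipeline, and reports recovery/calibration summaries.
These back both the validation test-suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from neuropheno import calcium as ca
from neuropheno import mea
from neuropheno import puncta as pt
from neuropheno import scstats as sc
from neuropheno.mea.network import acg_flatness
from neuropheno.mea.sort import sort_spike_table
from neuropheno.synth import (
    CalciumSimConfig,
    CountsSimConfig,
    MEASimConfig,
    PunctaSimConfig,
    gen_calcium,
    gen_counts,
    gen_mea,
    gen_puncta,
)
from neuropheno.synth.calcium import kernel_peak_time, transient_kernel
from neuropheno.synth.counts import gene_names


# ------------------------------------------------------------------ MEA


def _ground_truth_pct_outside(truth) -> float:
    w = truth["burst_windows"]
    t = truth["spikes"]["time_s"].to_numpy()
    inside = np.zeros(t.size, bool)
    for s, e in w:
        inside |= (t >= s) & (t <= e)
    return 100.0 * (1.0 - inside.mean())


def _network_summary(table: pd.DataFrame, duration: float):
    unit_stats = mea.spike_burst_stats(table, duration=duration)
    pct = float(
        np.average(unit_stats["pct_outside_bursts"], weights=unit_stats["n_spikes"])
    )
    trains = [g["time_s"].to_numpy() for _, g in table.groupby(["electrode", "unit"])]
    lags, macg = mea.mean_autocorrelogram(trains)
    return pct, mea.estimate_period(lags, macg), acg_flatness(lags, macg)


def mea_recovery(seeds=range(10)) -> dict:
    """Sorting + burst + period recovery on the default bursting network
    (8 electrodes × 3 units, 300 s, 9 s population-burst period)."""
    correct_units = 0
    n_electrodes = 0
    periods, pct_errors = [], []
    for seed in seeds:
        cfg = MEASimConfig(seed=int(seed))
        table, truth = gen_mea(cfg)
        sorted_t = sort_spike_table(table)
        n_units = sorted_t.groupby("electrode")["unit"].nunique()
        correct_units += int((n_units == cfg.units_per_electrode).sum())
        n_electrodes += len(n_units)
        pct, period, _ = _network_summary(sorted_t, cfg.duration)
        periods.append(period)
        pct_errors.append(abs(pct - _ground_truth_pct_outside(truth)))
    return {
        "unit_accuracy_frac": correct_units / n_electrodes,
        "n_electrodes": n_electrodes,
        "periods_s": periods,
        "pct_outside_abs_errors": pct_errors,
    }


def synchrony_discrimination(seeds=range(10)) -> dict:
    """Periodic-burst vs rate-matched Poisson: fraction of seeds where
    the synchronized culture has lower percent-outside-bursts and a less
    flat (more periodic) mean autocorrelogram."""
    wins = 0
    for seed in seeds:
        sync_cfg = MEASimConfig(n_electrodes=4, seed=int(seed))
        sync, _ = gen_mea(sync_cfg)
        rate = len(sync) / (sync_cfg.duration * 4 * sync_cfg.units_per_electrode)
        desync, _ = gen_mea(
            MEASimConfig(
                n_electrodes=4,
                burst_period=0.0,
                background_rate=rate,
                seed=int(seed) + 10_000,
            )
        )
        pct_s, _, flat_s = _network_summary(sync, sync_cfg.duration)
        pct_d, _, flat_d = _network_summary(desync, sync_cfg.duration)
        wins += int(pct_s < pct_d and flat_s > flat_d)
    return {"ordering_frac": wins / len(list(seeds)), "n_seeds": len(list(seeds))}


def reference_max_interval(times, p=None):
    """Brute-force Max-Interval reference: direct ISI scan, kept
    independent of :mod:`neuropheno.mea.bursts`."""
    from neuropheno.mea.bursts import MaxIntervalParams

    p = p or MaxIntervalParams()
    t = [float(v) for v in times]
    raw, open_, first = [], False, None
    for i in range(1, len(t)):
        isi = t[i] - t[i - 1]
        if not open_ and isi <= p.isi_start:
            open_, first = True, i - 1
        elif open_ and isi > p.isi_end:
            raw.append((first, i - 1))
            open_, first = False, None
    if open_:
        raw.append((first, len(t) - 1))
    merged = []
    for a, b in raw:
        if merged and t[a] - t[merged[-1][1]] < p.min_ibi:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return [
        (t[a], t[b], b - a + 1)
        for a, b in merged
        if b - a + 1 >= p.min_spikes and t[b] - t[a] >= p.min_duration
    ]


def burst_oracle(n_trains: int = 1000, seed: int = 0) -> dict:
    """Exact agreement of detect_bursts with the brute-force reference
    on random trains (Poisson, bursty and tie-heavy)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_trains):
        kind = i % 4
        if kind == 0:
            t = np.sort(rng.uniform(0, 30, rng.integers(0, 40)))
        elif kind == 1:
            t = np.sort(np.cumsum(rng.exponential(0.2, rng.integers(2, 150))))
        elif kind == 2:
            chunks, start = [], 0.0
            for _ in range(rng.integers(1, 8)):
                start += rng.exponential(2.0) + 0.3
                chunks.append(start + np.sort(rng.uniform(0, 0.5, rng.integers(1, 12))))
            t = np.sort(np.concatenate(chunks))
        else:
            base = np.arange(0, 3.0, 0.17)
            t = np.sort(rng.choice(base, size=rng.integers(2, 20)))
        got = mea.detect_bursts(t)
        ref = reference_max_interval(t)
        ok = len(got) == len(ref) and all(
            np.isclose(r.start_s, s) and np.isclose(r.end_s, e) and r.n_spikes == n
            for r, (s, e, n) in zip(got.itertuples(index=False), ref)
        )
        agree += int(ok)
    return {"agreement_frac": agree / n_trains, "n_trains": n_trains}


# -------------------------------------------------------------- calcium


def calcium_recovery(seed: int = 0, noise_fracs=(0.0, 0.05, 0.10)) -> dict:
    """Rate/t1/t2 recovery vs the analytic double-exponential crossings,
    plus pure-noise false-positive rate and k-monotonicity."""
    from scipy.optimize import brentq

    rate_err, t1_err, t2_err = [], [], []
    for i, nf in enumerate(noise_fracs):
        cfg = CalciumSimConfig(noise_sd=nf * 100.0, seed=seed + i)  # baseline 100
        traces, truth = gen_calcium(cfg)
        d = ca.dff(traces.to_numpy(), cfg.frame_rate)
        det = ca.detect_transients(d, cfg.frame_rate)
        n_true = len(truth["transients"])
        rate_err.append(abs(len(det) / n_true - 1.0))

        sigma = max(nf * cfg.amplitude, 0.02)
        tp = kernel_peak_time(cfg.rise_tau, cfg.decay_tau)
        f = lambda t: transient_kernel(np.array([t]), cfg.rise_tau, cfg.decay_tau)[0] - 0.5 * sigma
        t_on, t_ret = brentq(f, 1e-9, tp), brentq(f, tp, 1e4)
        ok = det[~det["censored"]]
        t1_err.append(abs(float(np.mean(det["t1_s"])) / (tp - t_on) - 1.0))
        t2_err.append(abs(float(np.mean(ok["t2_s"])) / (t_ret - tp) - 1.0))

    noise_cfg = CalciumSimConfig(
        n_rois=30, duration=300, transient_rate=0.0, noise_sd=5.0, seed=seed + 100
    )
    traces, _ = gen_calcium(noise_cfg)
    det = ca.detect_transients(ca.dff(traces.to_numpy(), noise_cfg.frame_rate), noise_cfg.frame_rate)
    fp_rate = 60.0 * len(det) / (noise_cfg.n_rois * noise_cfg.duration)

    mono_cfg = CalciumSimConfig(n_rois=5, seed=seed + 200)
    traces, _ = gen_calcium(mono_cfg)
    d = ca.dff(traces.to_numpy(), mono_cfg.frame_rate)
    counts = [
        len(ca.detect_transients(d, mono_cfg.frame_rate, k=k)) for k in (1, 2, 4, 8)
    ]
    return {
        "rate_rel_errors": rate_err,
        "t1_rel_errors": t1_err,
        "t2_rel_errors": t2_err,
        "false_positive_per_min": fp_rate,
        "k_monotonic": all(a >= b for a, b in zip(counts, counts[1:])),
    }


# --------------------------------------------------------------- puncta


def puncta_recovery(seeds=range(10), fractions=(0.0, 0.3, 0.6, 1.0)) -> dict:
    """Slope of measured percent-assigned against the planted
    colocalization fraction, and the shuffled-post chance control."""
    planted, measured = [], []
    for seed in seeds:
        for j, f in enumerate(fractions):
            cfg = PunctaSimConfig(
                coloc_fraction=f,
                seed=int((int(seed) * len(fractions) + j) % (2**31 - 1)),
            )
            img, _ = gen_puncta(cfg)
            pre = pt.detect_spots(img[0], cfg.spot_sigma, cfg.pixel_size)
            post = pt.detect_spots(img[1], cfg.spot_sigma, cfg.pixel_size)
            res = pt.assign(pre, post, max_dist_um=cfg.coloc_radius)
            planted.append(100.0 * f)
            measured.append(res["pct_assigned"])
    slope = float(np.polyfit(planted, measured, 1)[0])

    # chance control: post positions shuffled uniformly in the mask.
    # Expected assignment probability per pre spot is |disk ∩ mask| / A;
    # it reduces to the closed form 1-(1-πd²/A)^n_post when the disk lies
    # fully inside the mask, and is counted on the pixel grid otherwise
    # (thin processes clip the disks at their edges).
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(int(list(seeds)[0]) % (2**31 - 1))
    cfg = PunctaSimConfig(coloc_fraction=0.6, seed=1234)
    img, truth = gen_puncta(cfg)
    mask = truth["mask"]
    pre = pt.detect_spots(img[0], cfg.spot_sigma, cfg.pixel_size)
    area_px = np.argwhere(mask)
    d = cfg.coloc_radius
    n_rep, hits = 25, 0
    for _ in range(n_rep):
        pick = area_px[rng.integers(area_px.shape[0], size=cfg.n_post)]
        post = pd.DataFrame(
            {
                "x_um": pick[:, 1] * cfg.pixel_size,
                "y_um": pick[:, 0] * cfg.pixel_size,
            }
        )
        hits += pt.assign(pre, post, max_dist_um=d)["n_assigned"]

    tree = cKDTree(area_px * cfg.pixel_size)
    pre_rc = pre[["y_um", "x_um"]].to_numpy()
    n_near = np.array([len(tree.query_ball_point(p, d)) for p in pre_rc])
    p_hit = 1.0 - (1.0 - n_near / area_px.shape[0]) ** cfg.n_post
    expected = n_rep * p_hit.sum()
    se = np.sqrt(n_rep * np.sum(p_hit * (1 - p_hit)))
    total = len(pre) * n_rep
    area_um2 = mask.sum() * cfg.pixel_size**2
    return {
        "slope": slope,
        "chance_obs_frac": hits / total,
        "chance_expected_frac": expected / total,
        "chance_ideal_frac": 1.0 - (1.0 - np.pi * d**2 / area_um2) ** cfg.n_post,
        "chance_z": abs(hits - expected) / se,
        "n_images": len(planted),
    }


# ------------------------------------------------------------ statistics


def stats_oracles(seed: int = 0) -> dict:
    """Closed-form and enumeration checks plus null type-I calibration."""
    import itertools
    import math

    # hypergeometric vs exhaustive enumeration for small universes
    max_err = 0.0
    for N, K, n in [(8, 3, 4), (10, 5, 4), (12, 6, 5)]:
        for k_obs in range(min(K, n) + 1):
            cell = set(range(k_obs)) | set(range(K, K + n - k_obs))
            _, p = sc.hypergeom_enrich(cell, set(range(K)), N)
            hits = sum(
                len(set(range(K)).intersection(draw)) >= k_obs
                for draw in itertools.combinations(range(N), n)
            )
            max_err = max(max_err, abs(p - hits / math.comb(N, n)))

    norm = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["g"], columns=list("abcdef"))
    wilcoxon_p = float(sc.wilcoxon_de(norm, list("abc"), list("def"))["p"].iloc[0])
    bh = sc.bh_adjust([0.01, 0.02, 0.03, 0.04])
    chi2, _, _ = sc.chi_square([[30, 70], [50, 50]])

    cfg = CountsSimConfig(n_genes=5000, n_cells_per_group=200, seed=seed)
    counts, meta, _ = gen_counts(cfg)
    nrm = sc.normalize(counts)
    res = sc.wilcoxon_de(
        nrm,
        list(meta.index[meta["group"] == "WT"]),
        list(meta.index[meta["group"] == "KO"]),
    )
    return {
        "hypergeom_max_abs_err": max_err,
        "wilcoxon_exact_p": wilcoxon_p,
        "bh_example": list(bh),
        "chi2_example": float(chi2),
        "type1_error": float((res["p"] < 0.05).mean()),
        "n_null_genes": cfg.n_genes,
    }


def signature_pipeline(
    seeds=range(10), n_null_seeds: int = 200, null_base: int = 50_000
) -> dict:
    """Planted active-fraction discrimination (0.5 vs 0.1) and the
    identical-groups chi-square null calibration."""
    genes = gene_names(2000)
    sig = {"s": genes[:50]}
    wins = 0
    for seed in seeds:
        cfg = CountsSimConfig(
            n_genes=2000,
            n_cells_per_group=300,
            signature_genes=sig,
            active_fraction_per_group={"WT": 0.1, "KO": 0.5},
            seed=int(seed),
        )
        counts, meta, _ = gen_counts(cfg)
        _, props = sc.enrichment_table(
            sc.normalize(counts), sig, groups=meta["group"]
        )
        pr = props.set_index("group")["prop_enriched"]
        wins += int(pr["KO"] > pr["WT"] and props["chi2_p"].iloc[0] < 0.01)

    null_genes = gene_names(300)
    null_sig = {"s": null_genes[:20]}
    ps = []
    for s in range(n_null_seeds):
        cfg = CountsSimConfig(
            n_genes=300,
            n_cells_per_group=150,
            signature_genes=null_sig,
            active_fraction_per_group={"WT": 0.3, "KO": 0.3},
            seed=int((null_base + s) % (2**31 - 1)),
        )
        counts, meta, _ = gen_counts(cfg)
        _, props = sc.enrichment_table(
            sc.normalize(counts), null_sig, groups=meta["group"], n_top=60
        )
        ps.append(props["chi2_p"].iloc[0])
    ps = np.asarray(ps)
    ks_p = float(sps.kstest(ps[~np.isnan(ps)], "uniform").pvalue)
    return {
        "discrimination_frac": wins / len(list(seeds)),
        "null_ks_p": ks_p,
        "n_seeds": len(list(seeds)),
        "n_null_seeds": n_null_seeds,
    }
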