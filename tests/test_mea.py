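"""MEA pipeline: detection, sorting, Max-Interval bursts and network
metrics against hand-enumerated and simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from conftest import random_spike_train, reference_max_interval
from neuropheno import mea
from neuropheno.mea.network import acg_flatness
from neuropheno.mea.sort import sort_spike_table
from neuropheno.synth import MEASimConfig, gen_mea
from neuropheno.synth.mea import WaveformTemplate

HAND_TRAIN = np.array([0, 0.05, 0.10, 0.15, 2.0, 5.0, 5.06, 5.12, 5.18, 5.24])


class TestDetectBursts:
    def test_hand_enumerated_example(self):
        b = mea.detect_bursts(HAND_TRAIN)
        assert len(b) == 2
        assert b.iloc[0].tolist() == [0.0, 0.15, 4]
        assert b.iloc[1].tolist() == [5.0, 5.24, 5]

    def test_single_spike_empty(self):
        assert len(mea.detect_bursts(np.array([1.0]))) == 0
        assert len(mea.detect_bursts(np.array([]))) == 0

    def test_sparse_poisson_no_bursts(self, rng):
        # 0.1 Hz: P(ISI <= 0.17 s) = 1.7e-2... three in a row is vanishing
        t = np.sort(rng.uniform(0, 1000, 100))
        while np.any(np.diff(t) <= 0.17):
            t = np.sort(rng.uniform(0, 1000, 100))
        assert len(mea.detect_bursts(t)) == 0

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            mea.detect_bursts(np.array([1.0, 0.5, 2.0]))

    def test_agrees_with_reference_on_random_trains(self, rng):
        for _ in range(300):
            t = random_spike_train(rng)
            got = mea.detect_bursts(t)
            ref = reference_max_interval(t)
            assert len(got) == len(ref)
            for row, (s, e, n) in zip(got.itertuples(index=False), ref):
                assert row.start_s == pytest.approx(s)
                assert row.end_s == pytest.approx(e)
                assert row.n_spikes == n


class TestSpikeBurstStats:
    def test_rate_and_burst_means(self):
        import pandas as pd

        table = pd.DataFrame(
            {"electrode": 0, "unit": 0, "time_s": HAND_TRAIN}
        )
        stats = mea.spike_burst_stats(table, duration=50.0)
        row = stats.iloc[0]
        assert row["firing_rate_hz"] == pytest.approx(10 / 50)
        assert row["mean_burst_duration_s"] == pytest.approx((0.15 + 0.24) / 2)
        assert row["mean_spikes_per_burst"] == pytest.approx(4.5)

    def test_no_bursts_reported_as_nan(self):
        import pandas as pd

        table = pd.DataFrame(
            {"electrode": 0, "unit": 0, "time_s": [1.0, 10.0, 20.0, 30.0]}
        )
        stats = mea.spike_burst_stats(table, duration=40.0)
        assert np.isnan(stats.iloc[0]["mean_burst_duration_s"])
        assert stats.iloc[0]["n_bursts"] == 0

    def test_hundred_spikes_two_hz(self, rng):
        import pandas as pd

        table = pd.DataFrame(
            {"electrode": 0, "unit": 0, "time_s": np.sort(rng.uniform(0, 50, 100))}
        )
        stats = mea.spike_burst_stats(table, duration=50.0)
        assert stats.iloc[0]["firing_rate_hz"] == pytest.approx(2.0)


class TestPctOutsideBursts:
    def test_hand_example_ten_percent(self):
        bursts = mea.detect_bursts(HAND_TRAIN)
        assert mea.pct_outside_bursts(HAND_TRAIN, bursts) == pytest.approx(10.0)

    def test_all_inside_zero(self):
        t = np.array([0, 0.05, 0.10, 0.15])
        assert mea.pct_outside_bursts(t, mea.detect_bursts(t)) == 0.0

    def test_no_bursts_hundred(self):
        t = np.array([0.0, 10.0, 20.0])
        assert mea.pct_outside_bursts(t, mea.detect_bursts(t)) == 100.0

    def test_empty_train_nan(self):
        import pandas as pd

        assert np.isnan(
            mea.pct_outside_bursts(np.array([]), pd.DataFrame(columns=["start_s", "end_s"]))
        )


class TestAsdr:
    def test_two_trains_example(self):
        series = mea.asdr([np.array([0.5, 1.5]), np.array([0.6])], duration=2.0, bin_s=1.0)
        assert series.tolist() == [2, 1]

    def test_empty_array_all_zero(self):
        assert mea.asdr([], duration=3.0).tolist() == [0, 0, 0]

    def test_bad_bin(self):
        with pytest.raises(ValueError):
            mea.asdr([], duration=1.0, bin_s=0)

    @given(
        st.lists(
            st.lists(st.floats(0, 99.9, allow_nan=False), max_size=50), max_size=4
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, trains):
        arrs = [np.sort(np.asarray(t)) for t in trains]
        total = sum(len(t) for t in trains)
        assert mea.asdr(arrs, duration=100.0).sum() == total

    def test_bursting_has_higher_cv_than_poisson(self):
        sync, _ = gen_mea(MEASimConfig(n_electrodes=2, duration=120, seed=0))
        rate = len(sync) / (120 * 2 * 3)
        desync, _ = gen_mea(
            MEASimConfig(
                n_electrodes=2, duration=120, burst_period=0.0,
                background_rate=rate, seed=1,
            )
        )
        def cv(tab):
            s = mea.asdr(tab, duration=120)
            return s.std() / s.mean()
        assert cv(sync) > cv(desync)


class TestAutocorrelogram:
    def test_periodic_train_mass_at_integer_lags(self):
        t = np.arange(0, 100, 1.0)
        lags, acg = mea.autocorrelogram(t, bin_s=0.1, max_lag=5.0)
        nz = lags[acg > 0]
        assert np.allclose(nz, np.round(nz))

    def test_poisson_flat(self, rng):
        t = np.sort(rng.uniform(0, 600, rng.poisson(5 * 600)))
        lags, acg = mea.autocorrelogram(t, bin_s=0.1, max_lag=15.0, normalize=False)
        tail = acg[np.abs(lags) > 0.3]
        assert tail.max() / np.median(tail) < 1.5

    def test_too_few_spikes_zero(self):
        lags, acg = mea.autocorrelogram(np.array([1.0]))
        assert not acg.any()

    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, times):
        t = np.sort(np.asarray(times))
        lags, acg = mea.autocorrelogram(t, bin_s=0.25, max_lag=10.0, normalize=False)
        assert np.allclose(acg, acg[::-1])


class TestEstimatePeriod:
    def test_periodic_two_seconds(self):
        t = np.arange(0, 100, 2.0)
        lags, acg = mea.autocorrelogram(t, bin_s=0.1, max_lag=15.0)
        assert mea.estimate_period(lags, acg) == pytest.approx(2.0, abs=0.1)

    def test_bursting_network_recovers_period(self):
        table, _ = gen_mea(MEASimConfig(n_electrodes=4, duration=300, seed=11))
        trains = [g["time_s"].to_numpy() for _, g in table.groupby(["electrode", "unit"])]
        lags, macg = mea.mean_autocorrelogram(trains)
        assert 8.0 <= mea.estimate_period(lags, macg) <= 10.0

    def test_poisson_network_none(self, rng):
        trains = [np.sort(rng.uniform(0, 600, rng.poisson(5 * 600))) for _ in range(6)]
        lags, macg = mea.mean_autocorrelogram(trains)
        assert mea.estimate_period(lags, macg) is None


class TestDetectSpikes:
    def test_gaussian_noise_few_false_positives(self, rng):
        trace = rng.normal(0, 5, size=int(10 * 20000))
        assert len(mea.detect_spikes(trace, 20000, k=5)) < 5

    def test_single_planted_template(self):
        fs = 40000
        noise_sd = 5.0
        rng = np.random.default_rng(2)
        tmpl = WaveformTemplate(amplitude_uv=10 * noise_sd).render(fs)
        trace = rng.normal(0, noise_sd, size=int(5 * fs))
        pos = int(2.5 * fs)
        trace[pos : pos + len(tmpl)] += tmpl
        det = mea.detect_spikes(trace, fs, k=5)
        assert len(det) == 1
        planted_t = (pos + len(tmpl) // 3) / fs
        assert abs(det["time_s"].iloc[0] - planted_t) <= 1e-4

    def test_recall_on_planted_spikes(self, rng):
        fs = 20000
        trace = rng.normal(0, 5, size=int(60 * fs))
        tmpl = WaveformTemplate(amplitude_uv=40).render(fs)
        times = np.sort(rng.uniform(1, 59, 100))
        times = times[np.concatenate([[True], np.diff(times) > 0.01])]
        for tt in times:
            s = int(tt * fs)
            trace[s : s + len(tmpl)] += tmpl
        det = mea.detect_spikes(trace, fs, k=5)
        dt = det["time_s"].to_numpy()
        trough = (len(tmpl) // 3) / fs
        hits = sum(np.min(np.abs(dt - (tt + trough))) < 1e-3 for tt in times)
        assert hits / len(times) >= 0.99

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            mea.detect_spikes(np.zeros(10), 20000)


class TestSortUnits:
    @staticmethod
    def _instances(rng, amplitudes, n_each, noise_frac=0.05, fs=20000):
        X, y = [], []
        for i, a in enumerate(amplitudes):
            tmpl = WaveformTemplate(amplitude_uv=a).render(fs)
            X.append(tmpl + rng.normal(0, noise_frac * a, size=(n_each, tmpl.size)))
            y.extend([i] * n_each)
        return np.vstack(X), np.asarray(y)

    def test_single_template_one_cluster(self, rng):
        X, _ = self._instances(rng, [80.0], 200)
        sorter = mea.WaveformSorter().fit(X)
        assert sorter.n_units_ == 1

    def test_three_templates_recovered(self, rng):
        X, y = self._instances(rng, [40.0, 80.0, 160.0], 100)
        labels = mea.sort_units(X)
        assert adjusted_rand_score(y, labels) >= 0.95

    def test_deterministic(self, rng):
        X, _ = self._instances(rng, [40.0, 120.0], 80)
        assert np.array_equal(mea.sort_units(X), mea.sort_units(X))

    def test_too_few_waveforms_single_unit(self, rng):
        X, _ = self._instances(rng, [80.0], 5)
        with pytest.warns(UserWarning):
            labels = mea.sort_units(X)
        assert set(labels) == {0}


class TestEndToEnd:
    def test_unit_count_period_and_burst_recovery(self):
        cfg = MEASimConfig(seed=5)  # 8 electrodes x 3 units, 300 s, 9 s
        table, truth = gen_mea(cfg)
        sorted_t = sort_spike_table(table)
        n_units = sorted_t.groupby("electrode")["unit"].nunique()
        assert (n_units == 3).mean() >= 0.9

        stats = mea.spike_burst_stats(sorted_t, duration=cfg.duration)
        det_pct = np.average(stats["pct_outside_bursts"], weights=stats["n_spikes"])
        w = truth["burst_windows"]
        t = truth["spikes"]["time_s"].to_numpy()
        inside = np.zeros(t.size, bool)
        for s, e in w:
            inside |= (t >= s) & (t <= e)
        gt_pct = 100 * (1 - inside.mean())
        assert abs(det_pct - gt_pct) <= 5.0

        trains = [g["time_s"].to_numpy() for _, g in sorted_t.groupby(["electrode", "unit"])]
        lags, macg = mea.mean_autocorrelogram(trains)
        assert 8.0 <= mea.estimate_period(lags, macg) <= 10.0

    def test_synchronized_vs_poisson_ordering(self):
        sync, _ = gen_mea(MEASimConfig(n_electrodes=3, duration=200, seed=21))
        rate = len(sync) / (200 * 3 * 3)
        desync, _ = gen_mea(
            MEASimConfig(
                n_electrodes=3, duration=200, burst_period=0.0,
                background_rate=rate, seed=22,
            )
        )

        def summarize(tab):
            stats = mea.spike_burst_stats(tab, duration=200)
            pct = np.average(stats["pct_outside_bursts"], weights=stats["n_spikes"])
            trains = [g["time_s"].to_numpy() for _, g in tab.groupby(["electrode", "unit"])]
            lags, macg = mea.mean_autocorrelogram(trains)
            return pct, acg_flatness(lags, macg)

        pct_s, flat_s = summarize(sync)
        pct_d, flat_d = summarize(desync)
        assert pct_s < pct_d
        assert flat_s > flat_d
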