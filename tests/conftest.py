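import numpy as np
import pytest


@pytest.fixture()
def rng():
    # function-scoped so every test draws from the same fixed stream
    return np.random.default_rng(12345)


def reference_max_interval(
    times,
    isi_start=0.17,
    isi_end=0.3,
    min_ibi=0.2,
    min_spikes=3,
    min_duration=0.01,
):
    """Independent Max-Interval reference: explicit per-spike state machine.

    Used as the oracle for burst detection; deliberately written as a
    direct scan rather than sharing code with the implementation.
    """
    t = list(map(float, times))
    bursts = []
    in_burst = False
    first = None
    for i in range(1, len(t)):
        isi = t[i] - t[i - 1]
        if not in_burst:
            if isi <= isi_start:
                in_burst = True
                first = i - 1
        else:
            if isi > isi_end:
                bursts.append((first, i - 1))
                in_burst = False
                first = None
    if in_burst:
        bursts.append((first, len(t) - 1))

    merged = []
    for a, b in bursts:
        if merged and t[a] - t[merged[-1][1]] < min_ibi:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    out = []
    for a, b in merged:
        n = b - a + 1
        if n >= min_spikes and (t[b] - t[a]) >= min_duration:
            out.append((t[a], t[b], n))
    return out


def random_spike_train(rng, kind=None):
    """Random train mixing Poisson, bursty and pathological cases."""
    kind = kind if kind is not None else rng.integers(4)
    if kind == 0:  # sparse Poisson
        n = rng.integers(0, 30)
        return np.sort(rng.uniform(0, 30, n))
    if kind == 1:  # dense Poisson near the ISI thresholds
        n = rng.integers(2, 200)
        return np.sort(np.cumsum(rng.exponential(0.2, n)))
    if kind == 2:  # bursty
        t = []
        start = 0.0
        for _ in range(rng.integers(1, 10)):
            start += rng.exponential(2.0) + 0.3
            n = rng.integers(1, 12)
            t.extend(start + np.sort(rng.uniform(0, 0.5, n)))
        return np.sort(np.asarray(t))
    # ties and near-threshold ISIs
    base = np.sort(rng.choice(np.arange(0, 3.0, 0.17), size=rng.integers(2, 20)))
    return np.sort(np.concatenate([base, base[: rng.integers(0, 3)]]))
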