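"""Waveform-based spike sorting: PCA followed by a BIC-selected Gaussian
mixture, fitted independently per electrode."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


class WaveformSorter(BaseEstimator, ClusterMixin):
    """Cluster spike waveforms into putative single units.

    Waveforms are reduced to the first ``n_components`` principal
    components and clustered with Gaussian mixtures over
    ``k_range``; the number of units is chosen by BIC.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : unit label per waveform.
    n_units_ : selected number of mixture components.
    bic_ : dict mapping k to BIC.
    """

    def __init__(
        self,
        n_components: int = 3,
        k_range: tuple[int, int] = (1, 8),
        min_waveforms: int = 20,
        n_init: int = 3,
        random_state: int = 0,
    ) -> None:
        self.n_components = n_components
        self.k_range = k_range
        self.min_waveforms = min_waveforms
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.min_waveforms:
            msg = f"only {n} waveforms (<{self.min_waveforms}); assigning a single unit"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            self.labels_ = np.zeros(n, dtype=int)
            self.n_units_ = 1
            self.bic_ = {}
            return self

        n_pc = min(self.n_components, X.shape[1], n)
        self.pca_ = PCA(n_components=n_pc, random_state=self.random_state)
        Z = self.pca_.fit_transform(X)

        lo, hi = self.k_range
        hi = min(hi, n)
        self.bic_ = {}
        best = None
        for k in range(lo, hi + 1):
            gmm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                n_init=self.n_init,
                random_state=self.random_state,
                reg_covar=1e-4,
            ).fit(Z)
            self.bic_[k] = gmm.bic(Z)
            if best is None or self.bic_[k] < self.bic_[best[0]]:
                best = (k, gmm)
        self.n_units_ = best[0]
        self.gmm_ = best[1]
        self.labels_ = self.gmm_.predict(Z)
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def sort_units(
    waveforms: np.ndarray, k_range: tuple[int, int] = (1, 8), random_state: int = 0
) -> np.ndarray:
    """Sort one electrode's waveform matrix into unit labels."""
    return WaveformSorter(k_range=k_range, random_state=random_state).fit_predict(
        waveforms
    )


def sort_spike_table(
    table: pd.DataFrame, k_range: tuple[int, int] = (1, 8), random_state: int = 0
) -> pd.DataFrame:
    """Assign unit labels per electrode on a detected SpikeTable.

    Expects per-event waveforms in ``table.attrs['waveforms']``; returns
    a copy with a ``unit`` column (labels are per-electrode).
    """
    wf = table.attrs["waveforms"]
    out = table.copy()
    out["unit"] = -1
    for el, sub in table.groupby("electrode"):
        idx = sub.index.to_numpy()
        labels = WaveformSorter(
            k_range=k_range, random_state=random_state
        ).fit_predict(wf[idx])
        out.loc[idx, "unit"] = labels
    out.attrs = dict(table.attrs)
    return out
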