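"""Synaptic-puncta quantification: spot detection, dendrite (MAP2)
masking, and presynaptic→postsynaptic assignment yielding the percent of
presynaptic (SYP) spots with a postsynaptic (HOMER1) partner within a
distance threshold — a proxy for putative synaptic contacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian as gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


class SpotDetector(BaseEstimator):
    """Laplacian-of-Gaussian blob detector with sub-pixel centroids.

    The scale-normalized LoG response (``-σ²·∇²G⋆I``) is computed at the
    expected spot scale; local maxima above the ``threshold_quantile``
    of the response are kept and refined by a 3×3 center of mass.
    """

    def __init__(
        self,
        sigma_um: float = 0.2,
        pixel_size_um: float = 0.1,
        threshold_quantile: float = 0.995,
    ) -> None:
        self.sigma_um = sigma_um
        self.pixel_size_um = pixel_size_um
        self.threshold_quantile = threshold_quantile

    def transform(self, image: np.ndarray) -> pd.DataFrame:
        """Detect spots; returns a SpotSet DataFrame (x_um, y_um, intensity)."""
        img = np.asarray(image, dtype=float)
        if img.size and np.ptp(img) > 0 and np.mean(img >= img.max()) > 0.5:
            msg = "image looks saturated (>50% of pixels at max)"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        sigma_px = self.sigma_um / self.pixel_size_um
        response = -(sigma_px**2) * gaussian_laplace(img, sigma_px)
        thr = np.quantile(response, self.threshold_quantile)
        if response.max() <= thr or np.ptp(response) == 0:
            return pd.DataFrame(columns=["x_um", "y_um", "intensity"])
        peaks = peak_local_max(
            response,
            min_distance=max(int(round(2 * sigma_px)), 1),
            threshold_abs=thr,
            exclude_border=False,
        )
        cents = [self._refine(response, r, c) for r, c in peaks]
        cents_a = np.asarray(cents)
        return pd.DataFrame(
            {
                "x_um": cents_a[:, 1] * self.pixel_size_um,
                "y_um": cents_a[:, 0] * self.pixel_size_um,
                "intensity": img[peaks[:, 0], peaks[:, 1]],
            }
        )

    @staticmethod
    def _refine(response: np.ndarray, r: int, c: int) -> tuple[float, float]:
        h, w = response.shape
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        patch = response[r0:r1, c0:c1]
        patch = patch - patch.min()
        total = patch.sum()
        if total == 0:
            return float(r), float(c)
        ys, xs = np.mgrid[r0:r1, c0:c1]
        return float((ys * patch).sum() / total), float((xs * patch).sum() / total)


def detect_spots(
    image: np.ndarray,
    sigma_um: float,
    pixel_size_um: float,
    threshold_quantile: float = 0.995,
) -> pd.DataFrame:
    """LoG spot detection on one channel (thin wrapper)."""
    return SpotDetector(
        sigma_um=sigma_um,
        pixel_size_um=pixel_size_um,
        threshold_quantile=threshold_quantile,
    ).transform(image)


@dataclass
class NeuriteMask:
    mask: np.ndarray
    area_um2: float
    skeleton_length_um: float


def neurite_mask(
    map2: np.ndarray, pixel_size_um: float, smooth_um: float = 1.0
) -> NeuriteMask:
    """Otsu mask of the dendritic channel plus area and skeleton length.

    The channel is Gaussian-smoothed (1 µm) before thresholding; length
    sums the distances between adjacent skeleton pixels (diagonal steps
    count √2·pixel).
    """
    img = np.asarray(map2, dtype=float)
    if np.ptp(img) == 0:
        empty = np.zeros(img.shape, dtype=bool)
        return NeuriteMask(empty, 0.0, 0.0)
    smooth = gaussian_filter(img, sigma=smooth_um / pixel_size_um, preserve_range=True)
    mask = smooth > threshold_otsu(smooth)
    area = float(mask.sum()) * pixel_size_um**2
    skel = skeletonize(mask)
    length = _skeleton_length(skel)
    # skeletonization retracts each branch tip by roughly the local
    # half-width; add it back from the distance transform at endpoints
    length += _endpoint_correction(skel, mask)
    return NeuriteMask(mask, area, length * pixel_size_um)


def _endpoint_correction(skel: np.ndarray, mask: np.ndarray) -> float:
    """Half-width at each skeleton endpoint, in pixels."""
    from scipy.ndimage import convolve, distance_transform_edt

    neighbors = convolve(skel.astype(int), np.ones((3, 3), dtype=int), mode="constant")
    endpoints = skel & (neighbors == 2)  # self plus exactly one neighbor
    if not endpoints.any():
        return 0.0
    dist = distance_transform_edt(mask)
    return float(dist[endpoints].sum())


def _skeleton_length(skel: np.ndarray) -> float:
    """Sum of distances over adjacent (8-connected) skeleton pixel pairs,
    each unordered pair counted once."""
    h, w = skel.shape
    length = 0.0
    for dr, dc, d in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        a = skel[0 : h - dr, max(0, -dc) : w - max(0, dc)]
        b = skel[dr:h, max(0, dc) : w - max(0, -dc)]
        length += d * np.sum(a & b)
    return length


def assign(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    max_dist_um: float = 1.0,
    mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
    skeleton_length_um: float | None = None,
) -> dict:
    """Assign presynaptic spots to postsynaptic partners.

    A pre spot is assigned iff at least one post spot lies within
    ``max_dist_um`` (one post spot may serve several pre spots). When a
    mask is supplied (with its pixel size), spots outside it are dropped
    first and densities are normalized per 100 µm² of mask area (and per
    µm of skeleton length when given).

    Returns a dict with n_pre, n_post, pct_assigned (None when no pre
    spots), pairs (pre_id, post_id, distance_um of the nearest partner),
    and densities.
    """
    pre_xy = pre[["x_um", "y_um"]].to_numpy(dtype=float)
    post_xy = post[["x_um", "y_um"]].to_numpy(dtype=float)

    area_um2 = None
    if mask is not None:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a mask")
        pre_xy = _restrict(pre_xy, mask, pixel_size_um)
        post_xy = _restrict(post_xy, mask, pixel_size_um)
        area_um2 = float(mask.sum()) * pixel_size_um**2

    n_pre, n_post = len(pre_xy), len(post_xy)
    pairs = []
    assigned = np.zeros(n_pre, dtype=bool)
    if n_pre and n_post:
        tree = cKDTree(post_xy)
        dist, idx = tree.query(pre_xy, k=1, distance_upper_bound=max_dist_um)
        assigned = np.isfinite(dist)
        pairs = [
            (int(i), int(j), float(d))
            for i, (j, d) in enumerate(zip(idx, dist))
            if np.isfinite(d)
        ]

    result = {
        "n_pre": n_pre,
        "n_post": n_post,
        "n_assigned": int(assigned.sum()),
        "pct_assigned": (100.0 * assigned.mean()) if n_pre else None,
        "pairs": pairs,
        "pre_density_per_100um2": None,
        "post_density_per_100um2": None,
        "pre_density_per_um": None,
        "post_density_per_um": None,
    }
    if area_um2:
        result["pre_density_per_100um2"] = 100.0 * n_pre / area_um2
        result["post_density_per_100um2"] = 100.0 * n_post / area_um2
    if skeleton_length_um:
        result["pre_density_per_um"] = n_pre / skeleton_length_um
        result["post_density_per_um"] = n_post / skeleton_length_um
    return result


def _restrict(xy_um: np.ndarray, mask: np.ndarray, px: float) -> np.ndarray:
    if xy_um.size == 0:
        return xy_um
    cols = np.clip(np.round(xy_um[:, 0] / px).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(xy_um[:, 1] / px).astype(int), 0, mask.shape[0] - 1)
    return xy_um[mask[rows, cols]]
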