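"""Simulated synaptic-puncta images.

Three channels mimicking a presynaptic marker (SYP), a postsynaptic
marker (HOMER1) and a dendritic mask channel (MAP2). Spots are rendered
as Gaussian kernels inside a neurite-like mask built from random thick
segments. Exactly ``floor(coloc_fraction · n_pre)`` presynaptic spots
receive a postsynaptic partner within ``coloc_radius``; all other
pre/post pairs are kept farther apart than an exclusion margin so the
planted colocalization fraction is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PunctaSimConfig:
    image_shape: tuple[int, int] = (512, 512)  # px
    pixel_size: float = 0.1  # µm/px
    n_pre: int = 150
    n_post: int = 150
    coloc_fraction: float = 0.6
    coloc_radius: float = 0.5  # µm
    spot_sigma: float = 0.2  # µm
    snr: float = 10.0  # peak / noise SD; inf disables noise
    neurite_fraction: float = 0.3
    min_spot_spacing: float = 1.0  # µm, same-channel spots
    exclusion_margin: float = 2.0  # × coloc_radius, non-partner pre/post
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.coloc_radius <= 0 or self.spot_sigma <= 0:
            raise ValueError("coloc_radius and spot_sigma must be positive")


def _neurite_mask(cfg: PunctaSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Union of random thick segments covering ~neurite_fraction of the field."""
    h, w = cfg.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    half_width = 1.0 / cfg.pixel_size  # 2 µm wide processes
    target = cfg.neurite_fraction * h * w
    for _ in range(200):
        if mask.sum() >= target:
            break
        p0 = rng.uniform([0, 0], [h, w])
        ang = rng.uniform(0, np.pi)
        d = np.array([np.sin(ang), np.cos(ang)])
        # distance from pixel centers to the infinite line through p0
        rel_y, rel_x = yy - p0[0], xx - p0[1]
        dist = np.abs(rel_y * d[1] - rel_x * d[0])
        mask |= dist <= half_width
    return mask


def _sample_in_mask(
    mask_idx: np.ndarray, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    i = rng.integers(mask_idx.shape[0])
    return mask_idx[i].astype(float)  # (row, col) px


def _far_from(p: np.ndarray, pts: list[np.ndarray], min_d_px: float) -> bool:
    return all(np.hypot(*(p - q)) > min_d_px for q in pts)


def gen_puncta(config: PunctaSimConfig):
    """Simulate a 3-channel puncta image.

    Returns ``(image [3 x H x W float], ground_truth)`` with channels
    ordered pre, post, mask-proxy. Ground truth: pre/post centroids in
    µm (x, y), per-pre-spot partner flags, and the binary mask.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape
    mask = _neurite_mask(cfg, rng)
    mask_idx = np.argwhere(mask)
    if mask_idx.shape[0] == 0:
        raise ValueError("empty neurite mask; increase neurite_fraction")

    px = cfg.pixel_size
    spacing_px = cfg.min_spot_spacing / px
    margin_px = cfg.exclusion_margin * cfg.coloc_radius / px
    radius_px = cfg.coloc_radius / px
    n_pairs = int(np.floor(cfg.coloc_fraction * cfg.n_pre))

    pre: list[np.ndarray] = []
    post: list[np.ndarray] = []

    def place(constraint) -> np.ndarray:
        for _ in range(20000):
            p = _sample_in_mask(mask_idx, (h, w), rng)
            if constraint(p):
                return p
        raise RuntimeError("could not place spot inside mask under constraints")

    # partnered pre spots plus their posts
    for _ in range(n_pairs):
        p = place(
            lambda q: _far_from(q, pre, spacing_px) and _far_from(q, post, margin_px)
        )
        pre.append(p)
        for _ in range(20000):
            r = rng.uniform(0.15, 0.85) * radius_px
            ang = rng.uniform(0, 2 * np.pi)
            q = p + r * np.array([np.sin(ang), np.cos(ang)])
            qi = np.round(q).astype(int)
            if (
                0 <= qi[0] < h
                and 0 <= qi[1] < w
                and mask[qi[0], qi[1]]
                and _far_from(q, post, spacing_px)
            ):
                post.append(q)
                break
        else:
            raise RuntimeError("could not place partner post spot inside mask")

    # unpartnered pre spots: keep clear of every post
    for _ in range(cfg.n_pre - n_pairs):
        pre.append(
            place(
                lambda q: _far_from(q, pre, spacing_px)
                and _far_from(q, post, margin_px)
            )
        )
    # remaining post spots: keep clear of every pre
    for _ in range(cfg.n_post - n_pairs):
        post.append(
            place(
                lambda q: _far_from(q, post, spacing_px)
                and _far_from(q, pre, margin_px)
            )
        )

    pre_a = np.asarray(pre).reshape(cfg.n_pre, 2)
    post_a = np.asarray(post).reshape(cfg.n_post, 2)
    partnered = np.zeros(cfg.n_pre, dtype=bool)
    partnered[:n_pairs] = True

    noise_sd = 0.0 if np.isinf(cfg.snr) else 1.0
    amp = 1.0 if np.isinf(cfg.snr) else cfg.snr * noise_sd
    image = np.zeros((3, h, w))
    image[0] = _render(pre_a, cfg.spot_sigma / px, amp, (h, w))
    image[1] = _render(post_a, cfg.spot_sigma / px, amp, (h, w))
    image[2] = mask * (0.5 * amp)
    if noise_sd:
        image += rng.normal(0.0, noise_sd, size=image.shape)

    truth = {
        "pre_um": pre_a[:, ::-1] * px,  # (x, y) µm
        "post_um": post_a[:, ::-1] * px,
        "pre_has_partner": partnered,
        "n_partnered": n_pairs,
        "mask": mask,
        "config": cfg,
    }
    return image, truth


def _render(
    centers_px: np.ndarray, sigma_px: float, amp: float, shape: tuple[int, int]
) -> np.ndarray:
    h, w = shape
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma_px))
    for cy, cx in centers_px:
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        ys = np.arange(max(y0, 0), min(y1, h))
        xs = np.arange(max(x0, 0), min(x1, w))
        if ys.size == 0 or xs.size == 0:
            continue
        gy = np.exp(-0.5 * ((ys - cy) / sigma_px) ** 2)
        gx = np.exp(-0.5 * ((xs - cx) / sigma_px) ** 2)
        img[np.ix_(ys, xs)] += amp * np.outer(gy, gx)
    return img
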