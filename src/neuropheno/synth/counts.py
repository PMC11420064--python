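"""Simulated single-cell count matrices.

Negative-binomial counts parameterized by per-gene mean and dispersion
(var = µ + α·µ²), with log-normal library-size variation across cells.
Differential expression is planted by multiplying the mean of each DE
gene by ``2**log2fc`` in exactly one group; signature activation by
multiplying signature-gene means by ``activation_factor`` in a planted
fraction of cells per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountsSimConfig:
    n_genes: int = 2000
    n_cells_per_group: int = 300
    groups: tuple[str, ...] = ("WT", "KO")
    nb_mean: np.ndarray | float | None = None  # per-gene baseline means
    nb_dispersion: np.ndarray | float = 0.5
    de_genes: dict[str, float] = field(default_factory=dict)  # name -> log2FC in groups[1]
    signature_genes: dict[str, list[str]] = field(default_factory=dict)
    active_fraction_per_group: dict[str, float] = field(default_factory=dict)
    activation_factor: float = 4.0
    libsize_sd: float = 0.3  # log-normal sd of cell depth factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_group <= 0:
            raise ValueError("n_genes and n_cells_per_group must be positive")
        if self.activation_factor <= 0:
            raise ValueError("activation_factor must be positive")
        for g, f in self.active_fraction_per_group.items():
            if not 0 <= f <= 1:
                raise ValueError(f"active fraction for {g} must be in [0, 1]")


def gene_names(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def gen_counts(config: CountsSimConfig):
    """Simulate a gene × cell count matrix with metadata.

    Returns ``(counts DataFrame [genes x cells], meta DataFrame, ground_truth)``.
    Meta columns: ``group`` and one boolean ``active_<sig>`` per signature.
    Ground truth: ``de_genes`` (name -> planted log2FC), ``signatures``,
    per-cell activation flags, baseline means.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    if cfg.nb_mean is None:
        base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    else:
        base_mean = np.broadcast_to(
            np.asarray(cfg.nb_mean, dtype=float), (cfg.n_genes,)
        ).copy()
    disp = np.broadcast_to(
        np.asarray(cfg.nb_dispersion, dtype=float), (cfg.n_genes,)
    ).copy()

    unknown = [g for g in cfg.de_genes if g not in gene_idx]
    if unknown:
        raise ValueError(f"de_genes not in gene universe: {unknown[:3]}")
    for sig, members in cfg.signature_genes.items():
        missing = [g for g in members if g not in gene_idx]
        if missing:
            raise ValueError(f"signature {sig} genes missing: {missing[:3]}")

    n_cells = cfg.n_cells_per_group * len(cfg.groups)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    group_of = np.repeat(list(cfg.groups), cfg.n_cells_per_group)
    depth = rng.lognormal(mean=0.0, sigma=cfg.libsize_sd, size=n_cells)

    # per-group mean matrices: planted log2FC applies in groups[1] only
    group_mean = {g: base_mean.copy() for g in cfg.groups}
    alt = cfg.groups[1] if len(cfg.groups) > 1 else cfg.groups[0]
    for g, lfc in cfg.de_genes.items():
        group_mean[alt][gene_idx[g]] *= 2.0**lfc

    active = {
        sig: np.zeros(n_cells, dtype=bool) for sig in cfg.signature_genes
    }
    for sig in cfg.signature_genes:
        for gi, gname in enumerate(cfg.groups):
            frac = cfg.active_fraction_per_group.get(gname, 0.0)
            lo = gi * cfg.n_cells_per_group
            # Bernoulli per cell: the fraction is a population probability
            chosen = rng.random(cfg.n_cells_per_group) < frac
            active[sig][lo : lo + cfg.n_cells_per_group] = chosen

    counts = np.empty((cfg.n_genes, n_cells), dtype=np.int64)
    n_param = 1.0 / disp  # NB "number of successes"
    for c in range(n_cells):
        mu = group_mean[group_of[c]] * depth[c]
        for sig, members in cfg.signature_genes.items():
            if active[sig][c]:
                idx = [gene_idx[g] for g in members]
                mu = mu.copy()
                mu[idx] *= cfg.activation_factor
        p = n_param / (n_param + mu)
        counts[:, c] = rng.negative_binomial(n_param, p)

    counts_df = pd.DataFrame(counts, index=genes, columns=cell_ids)
    meta = pd.DataFrame({"group": group_of}, index=cell_ids)
    for sig, flags in active.items():
        meta[f"active_{sig}"] = flags

    truth = {
        "de_genes": dict(cfg.de_genes),
        "signatures": {k: list(v) for k, v in cfg.signature_genes.items()},
        "active": {k: v.copy() for k, v in active.items()},
        "base_mean": base_mean,
        "depth": depth,
        "config": cfg,
    }
    return counts_df, meta, truth
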