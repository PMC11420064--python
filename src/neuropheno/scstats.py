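"""Single-cell statistics: normalization, per-cell gene-set construction,
hypergeometric signature enrichment with BH correction and chi-square
group comparison, per-gene Wilcoxon (Mann-Whitney) differential
expression with log2FC thresholds, DEG-overlap tests, and the generic
rank/chi-square tests used by the other pipelines.

The per-cell enrichment follows the Cell-ID statistical contract — each
cell contributes a gene set that is tested against each signature with
an upper-tail hypergeometric test over a fixed universe — but builds the
per-cell set as the top-N genes by standardized expression rather than
by multiple-correspondence-analysis distance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEG_P_ADJ = 0.05
DEG_ABS_LOG2FC = 0.25


# ---------------------------------------------------------------- basic tests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    cell_set: set | list, signature: set | list, universe_size: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test.

    ``p = P(X >= k)`` with ``X ~ Hypergeom(N=universe_size,
    K=|signature|, n=|cell_set|)`` and ``k`` the observed overlap.
    An empty signature returns ``(0, 1.0)``.
    """
    cs, sig = set(cell_set), set(signature)
    if len(cs) > universe_size or len(sig) > universe_size:
        raise ValueError("sets larger than the universe")
    if not sig:
        return 0, 1.0
    k = len(cs & sig)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(sig), len(cs)))
    return k, min(p, 1.0)


def rank_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test. Returns (U, p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chi_square(table: np.ndarray, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test on a contingency table; returns (χ², df, p)."""
    table = np.asarray(table)
    if np.any(table < 0):
        raise ValueError("contingency table entries must be non-negative")
    res = stats.chi2_contingency(table, correction=yates)
    if np.any(res.expected_freq < 1):
        msg = "chi-square expected cell < 1; p-value unreliable"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def deg_overlap(
    list_a: list, list_b: list, universe_size: int
) -> tuple[int, float, float]:
    """Overlap between two DEG lists: (k, hypergeometric p, odds ratio).

    The odds ratio comes from the 2×2 universe-membership table with a
    Haldane 0.5 correction when any cell is zero.
    """
    a, b = set(list_a), set(list_b)
    if len(a | b) > universe_size:
        raise ValueError("universe smaller than the union of the lists")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))
    t11 = k
    t10 = len(a) - k
    t01 = len(b) - k
    t00 = universe_size - len(a | b)
    cells = np.array([t11, t10, t01, t00], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    odds = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return k, min(p, 1.0), float(odds)


# ------------------------------------------------------------- normalization


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize to the median cell depth, then log1p.

    ``counts`` is genes × cells. Zero-depth cells are dropped (logged).
    """
    depth = counts.sum(axis=0)
    zero = depth[depth == 0].index
    if len(zero):
        logger.info("dropping %d zero-depth cells", len(zero))
        counts = counts.drop(columns=zero)
        depth = depth.drop(zero)
    target = float(depth.median())
    scaled = counts * (target / depth)
    return np.log1p(scaled)


def per_cell_geneset(norm: pd.DataFrame, n_top: int = 200) -> pd.DataFrame:
    """Top-``n_top`` genes per cell by standardized expression.

    Expression is z-scored per gene across cells; ties break by gene
    order in the index, making the result invariant to input row
    permutations. Returns a boolean genes × cells membership frame.
    """
    if n_top > norm.shape[0]:
        raise ValueError("n_top exceeds the number of genes")
    sorted_genes = norm.index.sort_values()
    x = norm.loc[sorted_genes].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    # stable argsort on (-z, gene position): highest z first, gene order ties
    order = np.argsort(-z, axis=0, kind="stable")
    member = np.zeros(z.shape, dtype=bool)
    cols = np.arange(z.shape[1])
    member[order[:n_top], cols] = True
    out = pd.DataFrame(member, index=sorted_genes, columns=norm.columns)
    return out.loc[norm.index]


# ----------------------------------------------------------------- enrichment


def enrichment_table(
    norm: pd.DataFrame,
    signatures: dict[str, list[str]],
    groups: pd.Series | None = None,
    n_top: int = 200,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-cell signature enrichment with per-group proportions.

    For every cell × signature: hypergeometric overlap of the cell's
    top-``n_top`` gene set with the signature over the detected-gene
    universe; BH across cells within each signature;
    score = −log10(p_adj); ``enriched`` iff p_adj < ``alpha``.

    When ``groups`` is given, the second return value summarizes per
    group: proportion enriched plus a Pearson chi-square on the enriched
    × group contingency table (groups with <2 cells excluded, warned).
    """
    universe = norm.index[(norm > 0).any(axis=1)]
    n_universe = len(universe)
    member = per_cell_geneset(norm.loc[universe], n_top=n_top)

    cell_tables = []
    for name, genes in signatures.items():
        sig = [g for g in dict.fromkeys(genes) if g in set(universe)]
        sig_mask = member.index.isin(sig)
        k = member.to_numpy()[sig_mask].sum(axis=0)
        if len(sig) == 0:
            p = np.ones(member.shape[1])
        else:
            p = stats.hypergeom.sf(k - 1, n_universe, len(sig), n_top)
        p_adj = bh_adjust(p)
        cell_tables.append(
            pd.DataFrame(
                {
                    "cell": member.columns,
                    "signature": name,
                    "k": k,
                    "p": p,
                    "p_adj": p_adj,
                    "score": -np.log10(np.clip(p_adj, 1e-300, None)),
                    "enriched": p_adj < alpha,
                }
            )
        )
    table = pd.concat(cell_tables, ignore_index=True)

    if groups is None:
        return table, None

    groups = groups.loc[member.columns]
    sizes = groups.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        msg = f"excluding groups with <2 cells: {small}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    keep = ~groups.isin(small)

    rows = []
    for name in signatures:
        sub = table[table["signature"] == name].set_index("cell")
        enr = sub.loc[groups.index[keep], "enriched"].to_numpy()
        g = groups[keep].to_numpy()
        cont = pd.crosstab(g, enr).reindex(columns=[False, True], fill_value=0)
        cont_a = cont.to_numpy()
        if cont.shape[0] > 1 and (cont_a.sum(axis=0) > 0).all():
            chi2, dof, p = chi_square(cont_a)
        else:
            chi2, dof, p = np.nan, 0, np.nan
        for grp in cont.index:
            n_g = cont.loc[grp].sum()
            rows.append(
                {
                    "signature": name,
                    "group": grp,
                    "n_cells": int(n_g),
                    "prop_enriched": float(cont.loc[grp, True] / n_g),
                    "chi2": chi2,
                    "chi2_p": p,
                }
            )
    return table, pd.DataFrame(rows)


# -------------------------------------------------------- differential expr.


def _mannwhitney_vectorized(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided MWU, normal approximation with tie correction."""
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    both = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(both, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    # tie term per row: sum(t^3 - t) over tied groups
    srt = np.sort(both, axis=1)
    tie_term = np.empty(both.shape[0])
    for i in range(both.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        tie_term[i] = np.sum(counts.astype(float) ** 3 - counts)

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - mu) / np.sqrt(var)
    p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return u1, np.minimum(p, 1.0)


def wilcoxon_de(
    norm: pd.DataFrame,
    cells_a: list,
    cells_b: list,
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon (Mann-Whitney) differential expression.

    ``norm`` is the log1p-normalized genes × cells frame. log2FC follows
    the scanpy convention, ``log2((expm1(mean_a)+1e-9) /
    (expm1(mean_b)+1e-9))`` with means taken on the log scale. P-values
    are BH-adjusted across genes; a gene is a DEG iff p_adj < 0.05 and
    |log2FC| > 0.25. Exact enumeration is used when
    ``n_a + n_b <= exact_max_n``; all-zero genes get p = 1, log2FC = 0.
    """
    a = norm[list(cells_a)].to_numpy(dtype=float)
    b = norm[list(cells_b)].to_numpy(dtype=float)
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("need at least 3 cells per group")

    eps = 1e-9
    mean_a = np.expm1(a.mean(axis=1)) + eps
    mean_b = np.expm1(b.mean(axis=1)) + eps
    log2fc = np.log2(mean_a / mean_b)

    allzero = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    if a.shape[1] + b.shape[1] <= exact_max_n:
        u = np.empty(a.shape[0])
        p = np.empty(a.shape[0])
        for i in range(a.shape[0]):
            row = np.concatenate([a[i], b[i]])
            # the exact null distribution assumes untied ranks
            method = "exact" if np.unique(row).size == row.size else "asymptotic"
            res = stats.mannwhitneyu(
                a[i], b[i], alternative="two-sided", method=method
            )
            u[i], p[i] = res.statistic, res.pvalue
    else:
        u, p = _mannwhitney_vectorized(a, b)

    p = np.where(allzero, 1.0, p)
    log2fc = np.where(allzero, 0.0, log2fc)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": norm.index,
            "log2fc": log2fc,
            "U": u,
            "p": p,
            "p_adj": p_adj,
            "is_deg": (p_adj < DEG_P_ADJ) & (np.abs(log2fc) > DEG_ABS_LOG2FC),
        }
    ).set_index("gene")


def pseudobulk(counts: pd.DataFrame, sample_of: pd.Series) -> pd.DataFrame:
    """Aggregate counts per sample (column sums within sample labels).

    Export hook for count-model DE tools applied at the sample level;
    those models are not re-implemented here.
    """
    return counts.T.groupby(sample_of.loc[counts.columns]).sum().T
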