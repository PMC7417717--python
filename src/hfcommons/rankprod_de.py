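"""Tier 1: rank-product differential expression per comparison.

For one comparison, all ``n_disease * n_control`` pairwise log2 differences
are computed, each pair's vector is ranked across genes (descending for the
up direction, ascending for down, ties averaged), and the per-gene rank
product is the geometric mean of its ranks over all pairs, keeping values
comparable across comparisons with different numbers of pairs.

Significance comes from permutation: each permutation round independently
shuffles every sample's values across genes, recomputes all pairwise
ratios, ranks and rank products, yielding G null rank products per round.
Shuffling whole samples (rather than each ratio column separately) keeps
the correlation between ratio columns that share a sample, which is what
makes the null calibrated for the all-pairs design.  For an observed rank
product ``rho`` at ascending-sort position ``s``::

    c   = #{ null rank products <= rho, over all rounds }
    p   = c / (n_perm * G)                (floored at 1/(n_perm*G))
    pfp = (c / n_perm) / s                (expected false positives per call)

Genes with ``pfp < 0.05`` in a direction are called differentially
expressed; when both directions clear the threshold the smaller pfp wins
and an exact tie resolves to no call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io_formats import Comparison, ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "pairwise_log_ratios",
    "rank_product",
    "permutation_null",
    "call_degs",
    "run_comparison",
    "run_compendium",
]

PFP_THRESHOLD = 0.05


@dataclass
class DEResult:
    """Per-gene rank-product statistics for one comparison.

    ``table`` is indexed by gene with columns ``rp_up, rp_down, p_up,
    p_down, pfp_up, pfp_down, avg_log_ratio, call``.
    """

    comparison_id: str
    table: pd.DataFrame

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def degs(self) -> pd.Index:
        return self.table.index[self.table["call"] != "none"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "comparison_id", self.comparison_id)
        out.to_csv(path, sep="\t", index_label="gene", float_format="%.8g")


def pairwise_log_ratios(ds: ExpressionDataset, comparison: Comparison) -> pd.DataFrame:
    """All disease-minus-control log2 differences, one column per sample pair."""
    missing = [
        s
        for s in tuple(comparison.disease_samples) + tuple(comparison.control_samples)
        if s not in set(ds.matrix.columns)
    ]
    if missing:
        raise ValueError(f"missing sample(s) {missing[:5]} in dataset {ds.dataset_id}")
    disease = ds.matrix[list(comparison.disease_samples)].to_numpy(dtype=float)
    control = ds.matrix[list(comparison.control_samples)].to_numpy(dtype=float)
    n_genes, n_d = disease.shape
    n_c = control.shape[1]
    ratios = (disease[:, :, None] - control[:, None, :]).reshape(n_genes, n_d * n_c)
    columns = [f"{d}/{c}" for d in comparison.disease_samples for c in comparison.control_samples]
    return pd.DataFrame(ratios, index=ds.matrix.index, columns=columns)


def rank_product(ratio_table) -> tuple:
    """Geometric-mean fold-change ranks per gene, both directions.

    Returns ``(rp_up, rp_down)`` arrays; rank 1 in the up direction is the
    most disease-elevated gene of a pair.
    """
    ratios = np.asarray(ratio_table, dtype=float)
    if ratios.ndim != 2 or ratios.shape[1] < 1:
        raise ValueError("ratio table must be a genes x pairs matrix with K >= 1")
    if not np.all(np.isfinite(ratios)):
        raise ValueError("ratio table contains non-finite values")
    ranks_up = _sps.rankdata(-ratios, method="average", axis=0)
    ranks_down = _sps.rankdata(ratios, method="average", axis=0)
    rp_up = np.exp(np.log(ranks_up).mean(axis=1))
    rp_down = np.exp(np.log(ranks_down).mean(axis=1))
    return rp_up, rp_down


def _null_rank_products(disease: np.ndarray, control: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Sorted null rank products from per-sample value shuffles.

    Ranks within a shuffled ratio column are tie-free with probability one
    (random tie-breaking), so a fast double-argsort replaces tie-averaged
    ranking here.
    """
    n_genes, n_d = disease.shape
    data = np.hstack([disease, control])
    null = np.empty(n_perm * n_genes)
    for b in range(n_perm):
        shuffled = rng.permuted(data, axis=0)
        ratios = (shuffled[:, :n_d, None] - shuffled[:, None, n_d:]).reshape(n_genes, -1)
        order = np.argsort(-ratios, axis=0, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(1, n_genes + 1)[:, None], axis=0)
        null[b * n_genes : (b + 1) * n_genes] = np.exp(np.log(ranks).mean(axis=1))
    null.sort()
    return null


def permutation_null(disease, control, n_perm: int = 100, seed: int = 0, rng=None) -> dict:
    """Permutation p and pfp values for both directions of a comparison.

    ``disease``/``control`` are genes x samples value blocks.  The null
    rank products (one sorted pool across all rounds) are shared by both
    directions: their null laws coincide because shuffled ranks are
    exchangeable with their reversals.
    """
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    if disease.ndim != 2 or control.ndim != 2 or disease.shape[0] != control.shape[0]:
        raise ValueError("disease and control must be genes x samples blocks over the same genes")
    n_genes, n_d = disease.shape
    ratios = (disease[:, :, None] - control[:, None, :]).reshape(n_genes, -1)
    rp_up, rp_down = rank_product(ratios)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    null = _null_rank_products(disease, control, n_perm, rng)

    def one_side(rp: np.ndarray) -> tuple:
        c = np.searchsorted(null, rp, side="right").astype(float)
        p = np.maximum(c, 1.0) / (n_perm * n_genes)
        s = _sps.rankdata(rp, method="max")
        pfp = (c / n_perm) / s
        return p, pfp

    p_up, pfp_up = one_side(rp_up)
    p_down, pfp_down = one_side(rp_down)
    return {
        "rp_up": rp_up,
        "rp_down": rp_down,
        "p_up": p_up,
        "p_down": p_down,
        "pfp_up": pfp_up,
        "pfp_down": pfp_down,
    }


def call_degs(pfp_up, pfp_down, pfp_threshold: float = PFP_THRESHOLD) -> np.ndarray:
    """Direction calls; the smaller pfp wins, an exact tie yields no call."""
    pfp_up = np.asarray(pfp_up, dtype=float)
    pfp_down = np.asarray(pfp_down, dtype=float)
    call = np.full(pfp_up.shape, "none", dtype=object)
    up = (pfp_up < pfp_threshold) & (pfp_up < pfp_down)
    down = (pfp_down < pfp_threshold) & (pfp_down < pfp_up)
    call[up] = "up"
    call[down] = "down"
    ties = (pfp_up < pfp_threshold) & (pfp_up == pfp_down)
    if ties.any():
        logger.info("%d genes significant in both directions with tied pfp; left uncalled", int(ties.sum()))
    return call


def run_comparison(
    ds: ExpressionDataset,
    comparison: Comparison,
    n_perm: int = 100,
    seed: int = 0,
    pfp_threshold: float = PFP_THRESHOLD,
    rng=None,
) -> DEResult:
    """Full tier-1 analysis of one comparison."""
    ratio_table = pairwise_log_ratios(ds, comparison)
    disease = ds.matrix[list(comparison.disease_samples)].to_numpy(dtype=float)
    control = ds.matrix[list(comparison.control_samples)].to_numpy(dtype=float)
    stats = permutation_null(disease, control, n_perm=n_perm, seed=seed, rng=rng)
    table = pd.DataFrame(stats, index=ratio_table.index)
    table["avg_log_ratio"] = ratio_table.to_numpy().mean(axis=1)
    table["call"] = call_degs(stats["pfp_up"], stats["pfp_down"], pfp_threshold)
    return DEResult(comparison_id=comparison.comparison_id, table=table)


def run_compendium(comp, n_perm: int = 100, seed: int = 0, pfp_threshold: float = PFP_THRESHOLD) -> list:
    """Tier-1 analysis of every comparison, with per-comparison child seeds."""
    children = np.random.SeedSequence(seed).spawn(len(comp.comparisons))
    results = []
    for comparison, child in zip(comp.comparisons, children):
        ds = comp.dataset(comparison.dataset_id)
        rng = np.random.default_rng(child)
        results.append(run_comparison(ds, comparison, n_perm=n_perm, pfp_threshold=pfp_threshold, rng=rng))
        logger.info("comparison %s: %d DEGs", comparison.comparison_id, len(results[-1].degs()))
    return results
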