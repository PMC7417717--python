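"""Tier 2: per-disease-sample pre-ranked gene set enrichment.

Pipeline per disease sample:

1. ranking metric — the sample's log2 value minus the mean of its
   comparison's control samples, sorted descending (ties broken by stable
   gene-name order);
2. weighted-KS enrichment score (ES) — walking the ranked list, members of
   a set increment the running sum by ``|metric|^w / N_R`` and non-members
   decrement by ``1/(N - N_H)``; the ES is the running-sum value of maximal
   absolute magnitude, signed;
3. significance — gene-permutation null: random same-size sets drawn
   without replacement from the ranked universe, with add-one smoothing
   over the same-signed null scores.

Collections are pre-filtered: sets are intersected with the analysis
universe, size-filtered to ``[min_size, max_size]`` and pruned for
redundancy with the overlap coefficient ``|A & B| / min(|A|, |B|)``,
keeping the larger set of any pair exceeding the cutoff.

Significance is nominal ``p < 0.05`` per pathway per sample (no FDR
q-values); the consensus tier consumes these flags.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionCompendium, ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "FilteredCollection",
    "SampleEnrichment",
    "filter_collection",
    "sample_metric",
    "enrichment_score",
    "gene_permutation_p",
    "enrich_compendium",
]

MIN_SIZE = 5
MAX_SIZE = 300
OVERLAP_CUT = 0.8
ALPHA = 0.05


@dataclass
class FilteredCollection:
    """Gene sets surviving size and redundancy filters, with drop reasons."""

    collection: GeneSetCollection
    dropped: list

    @property
    def sets(self) -> dict:
        return self.collection.sets

    def __len__(self) -> int:
        return len(self.collection)


@dataclass
class SampleEnrichment:
    """Per-pathway ES / p / direction for one disease sample.

    ``table`` is indexed by pathway with columns ``es, p, significant,
    direction``.
    """

    sample_id: str
    comparison_id: str
    condition: str
    table: pd.DataFrame


def filter_collection(
    coll: GeneSetCollection,
    universe,
    min_size: int = MIN_SIZE,
    max_size: int = MAX_SIZE,
    overlap_cut: float = OVERLAP_CUT,
    exclude=None,
) -> FilteredCollection:
    """Apply the exclusion list, universe intersection, size window and
    overlap-coefficient redundancy pruning (larger set kept)."""
    if len(coll) == 0:
        raise ValueError("cannot filter an empty collection")
    universe = frozenset(universe)
    exclude = frozenset(exclude or ())
    dropped = []
    candidates = {}
    for name, genes in coll.sets.items():
        if name in exclude:
            dropped.append((name, "excluded by name"))
            continue
        restricted = genes & universe
        if len(restricted) < min_size:
            dropped.append((name, f"too small ({len(restricted)} < {min_size})"))
            continue
        if len(restricted) > max_size:
            dropped.append((name, f"too large ({len(restricted)} > {max_size})"))
            continue
        candidates[name] = restricted
    kept: dict = {}
    for name in sorted(candidates, key=lambda n: (-len(candidates[n]), n)):
        genes = candidates[name]
        clash = None
        for kept_name, kept_genes in kept.items():
            ratio = len(genes & kept_genes) / min(len(genes), len(kept_genes))
            if ratio > overlap_cut:
                clash = (kept_name, ratio)
                break
        if clash is None:
            kept[name] = genes
        else:
            dropped.append((name, f"overlap ratio {clash[1]:.3f} > {overlap_cut} with {clash[0]}"))
            logger.debug("dropping %s: %s", name, dropped[-1][1])
    ordered = {name: kept[name] for name in coll.sets if name in kept}
    return FilteredCollection(
        collection=GeneSetCollection(sets=ordered, provenance=f"{coll.provenance} [filtered]"),
        dropped=dropped,
    )


def sample_metric(ds: ExpressionDataset, disease_sample: str, control_samples=None) -> pd.Series:
    """Per-gene ranking metric: sample minus control mean, sorted descending.

    Ties are broken by stable ascending gene-name order.  A degenerate
    all-zero metric is flagged with a warning (the ES remains defined but
    its permutation p is meaningless).
    """
    controls = tuple(control_samples) if control_samples is not None else ds.control_samples
    if not controls:
        raise ValueError("sample_metric needs at least one control sample")
    metric = ds.matrix[disease_sample] - ds.matrix[list(controls)].mean(axis=1)
    values = metric.to_numpy(dtype=float)
    if np.all(values == 0.0):
        warnings.warn(f"degenerate all-zero metric for sample {disease_sample}", RuntimeWarning, stacklevel=2)
    order = np.lexsort((metric.index.to_numpy(), -values))
    return metric.iloc[order]


def enrichment_score(genes, metrics, gene_set, weight_exponent: float = 1.0) -> float:
    """Weighted-KS enrichment score of ``gene_set`` along a ranked list.

    ``genes``/``metrics`` are the ranked list (best-to-worst) with metric
    values; the set must be a non-empty strict subset of the list.
    """
    genes = np.asarray(list(genes), dtype=object)
    metrics = np.asarray(metrics, dtype=float)
    if genes.shape != metrics.shape:
        raise ValueError("genes and metrics must be parallel")
    members = frozenset(gene_set)
    mask = np.fromiter((g in members for g in genes), count=genes.size, dtype=bool)
    n_total = genes.size
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n_total:
        raise ValueError("gene set covers the entire ranked list")
    weights = np.abs(metrics[mask]) ** weight_exponent
    norm = weights.sum()
    if norm == 0.0:
        warnings.warn("all member metrics are zero; falling back to equal hit increments", RuntimeWarning, stacklevel=2)
        weights = np.ones(n_hit)
        norm = float(n_hit)
    steps = np.full(n_total, -1.0 / (n_total - n_hit))
    steps[mask] = weights / norm
    running = np.cumsum(steps)
    return _signed_extreme(float(running.max()), float(running.min()))


def _signed_extreme(max_val: float, min_val: float) -> float:
    """Running-sum value of maximal magnitude, preferring the positive
    extreme on (near-)exact magnitude ties so the rule is float-stable."""
    return max_val if max_val >= -min_val - 1e-12 else min_val


def _es_from_positions(positions: np.ndarray, abs_weights: np.ndarray, n_total: int) -> np.ndarray:
    """ES for many same-size sets given their sorted 0-based hit positions.

    Exploits the piecewise-linear running sum: the maximum is attained at a
    hit and the minimum just before a hit, so only ``m`` candidates per set
    need checking.  ``positions`` is (n_sets, m); ``abs_weights`` is the
    full |metric|^w vector in ranked order.
    """
    n_sets, m = positions.shape
    w = abs_weights[positions]
    norm = w.sum(axis=1, keepdims=True)
    degenerate = norm[:, 0] == 0.0
    if degenerate.any():
        w[degenerate] = 1.0
        norm = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / norm
    miss = (positions - np.arange(m)) / (n_total - m)
    max_cand = (cum - miss).max(axis=1)
    min_cand = (cum - w / norm - miss).min(axis=1)
    return np.where(max_cand >= -min_cand - 1e-12, max_cand, min_cand)


def _sample_positions(rng, n_sets: int, n_total: int, size: int) -> np.ndarray:
    """Sorted distinct 0-based positions for ``n_sets`` random draws without
    replacement; rejection sampling with an argpartition fallback for dense
    draws."""
    if size >= n_total:
        raise ValueError("set size must be smaller than the universe")
    if size * size > n_total:
        keys = rng.random((n_sets, n_total))
        pos = np.argpartition(keys, size, axis=1)[:, :size]
        pos.sort(axis=1)
        return pos
    pos = rng.integers(0, n_total, size=(n_sets, size))
    while True:
        pos.sort(axis=1)
        if size == 1:
            return pos
        bad = (np.diff(pos, axis=1) == 0).any(axis=1)
        if not bad.any():
            return pos
        pos[bad] = rng.integers(0, n_total, size=(int(bad.sum()), size))


def _null_es(abs_weights: np.ndarray, size: int, n_perm: int, rng) -> np.ndarray:
    positions = _sample_positions(rng, n_perm, abs_weights.size, size)
    return _es_from_positions(positions, abs_weights, abs_weights.size)


def _smoothed_p(null: np.ndarray, observed: float) -> float:
    """Add-one smoothed same-sign permutation p; 1.0 when no evidence."""
    if observed == 0.0:
        return 1.0
    same = null > 0.0 if observed > 0.0 else null < 0.0
    k = int(same.sum())
    if k == 0:
        return 1.0
    extreme = int((np.abs(null[same]) >= abs(observed)).sum())
    return (1 + extreme) / (1 + k)


def gene_permutation_p(metrics, gene_set_size: int, observed_es: float, n_perm: int = 1000, seed: int = 0, rng=None) -> float:
    """Gene-permutation nominal p for an observed ES.

    ``metrics`` is the ranked metric vector (the universe the null sets are
    drawn from); null sets of identical size are drawn without replacement.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    abs_weights = np.abs(np.asarray(metrics, dtype=float))
    null = _null_es(abs_weights, int(gene_set_size), n_perm, rng)
    return _smoothed_p(null, float(observed_es))


def _enrich_one_sample(ranked: pd.Series, filtered: FilteredCollection, n_perm: int, rng, alpha: float) -> pd.DataFrame:
    """ES/p for every surviving set against one ranked metric vector.

    Null ES distributions are shared across sets of equal size (they depend
    only on the metric vector and the set size).
    """
    gene_pos = {g: i for i, g in enumerate(ranked.index)}
    abs_weights = np.abs(ranked.to_numpy(dtype=float))
    n_total = abs_weights.size

    sizes: dict = {}
    set_positions: dict = {}
    for name, genes in filtered.sets.items():
        pos = np.sort(np.fromiter((gene_pos[g] for g in genes if g in gene_pos), dtype=int))
        if pos.size == 0 or pos.size >= n_total:
            continue
        set_positions[name] = pos
        sizes.setdefault(pos.size, []).append(name)

    null_by_size = {size: _null_es(abs_weights, size, n_perm, rng) for size in sorted(sizes)}

    rows = []
    for name, pos in set_positions.items():
        es = float(_es_from_positions(pos[None, :], abs_weights, n_total)[0])
        p = _smoothed_p(null_by_size[pos.size], es)
        direction = "up" if es > 0 else ("down" if es < 0 else "none")
        rows.append((name, es, p, bool(p < alpha and es != 0.0), direction))
    table = pd.DataFrame(rows, columns=["pathway", "es", "p", "significant", "direction"])
    return table.set_index("pathway")


def enrich_compendium(
    comp: ExpressionCompendium,
    coll: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = MIN_SIZE,
    max_size: int = MAX_SIZE,
    overlap_cut: float = OVERLAP_CUT,
    exclude=None,
    alpha: float = ALPHA,
) -> list:
    """Per-disease-sample enrichment across the whole compendium.

    The collection is filtered once per dataset against that dataset's gene
    universe; each disease sample gets an independent child seed so results
    do not depend on iteration order.
    """
    filtered_cache: dict = {}
    n_samples = sum(len(c.disease_samples) for c in comp.comparisons)
    children = iter(np.random.SeedSequence(seed).spawn(n_samples))
    out = []
    for comparison in comp.comparisons:
        ds = comp.dataset(comparison.dataset_id)
        if ds.dataset_id not in filtered_cache:
            filtered_cache[ds.dataset_id] = filter_collection(
                coll, ds.genes, min_size=min_size, max_size=max_size, overlap_cut=overlap_cut, exclude=exclude
            )
        filtered = filtered_cache[ds.dataset_id]
        for sample_id in comparison.disease_samples:
            rng = np.random.default_rng(next(children))
            ranked = sample_metric(ds, sample_id, comparison.control_samples)
            table = _enrich_one_sample(ranked, filtered, n_perm, rng, alpha)
            out.append(
                SampleEnrichment(
                    sample_id=sample_id,
                    comparison_id=comparison.comparison_id,
                    condition=comparison.condition,
                    table=table,
                )
            )
    logger.info("enriched %d disease samples against %d-set collection", len(out), len(coll))
    return out


def enrichment_to_frame(enrichments) -> pd.DataFrame:
    """Long-format table (sample_id, comparison_id, condition, pathway, ...)."""
    frames = []
    for enr in enrichments:
        t = enr.table.reset_index()
        t.insert(0, "condition", enr.condition)
        t.insert(0, "comparison_id", enr.comparison_id)
        t.insert(0, "sample_id", enr.sample_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
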