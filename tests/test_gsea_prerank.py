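import warnings

import numpy as np
import pandas as pd
import pytest

from hfcommons.gsea_prerank import (
    _es_from_positions,
    _null_es,
    _sample_positions,
    enrich_compendium,
    enrichment_score,
    filter_collection,
    gene_permutation_p,
    sample_metric,
)
from hfcommons.io_formats import ExpressionDataset, GeneSetCollection


def _es_oracle(genes, metrics, gene_set, w=1.0):
    """Independent walk: explicit python loop over the ranked list."""
    members = set(gene_set)
    n = len(genes)
    n_hit = sum(g in members for g in genes)
    norm = sum(abs(m) ** w for g, m in zip(genes, metrics) if g in members)
    running = 0.0
    rmax = rmin = 0.0
    for g, m in zip(genes, metrics):
        if g in members:
            running += (abs(m) ** w) / norm
        else:
            running -= 1.0 / (n - n_hit)
        rmax = max(rmax, running)
        rmin = min(rmin, running)
    # positive extreme preferred on magnitude ties (the package's tie rule)
    return rmax if rmax >= -rmin - 1e-12 else rmin


# ---------------------------------------------------------------------------
# filter_collection
# ---------------------------------------------------------------------------


def make_coll(**sets):
    return GeneSetCollection(sets={k: frozenset(v) for k, v in sets.items()})


def test_filter_too_small_dropped():
    coll = make_coll(S1=[f"g{i}" for i in range(4)], S2=[f"g{i}" for i in range(8)])
    out = filter_collection(coll, universe=[f"g{i}" for i in range(20)])
    assert "S1" not in out.sets and "S2" in out.sets
    assert any(name == "S1" and "too small" in reason for name, reason in out.dropped)


def test_filter_universe_intersection_counts():
    # size 6 set, but only 4 genes in universe -> dropped
    coll = make_coll(S1=[f"g{i}" for i in range(6)])
    out = filter_collection(coll, universe=["g0", "g1", "g2", "g3"] + [f"x{i}" for i in range(10)])
    assert len(out.sets) == 0


def test_filter_overlap_drops_smaller():
    big = [f"g{i}" for i in range(20)]
    small = big[:9] + ["h0"]
    coll = make_coll(A=big, B=small)
    out = filter_collection(coll, universe=big + ["h0"])
    assert "A" in out.sets and "B" not in out.sets
    assert any("overlap ratio" in reason for _, reason in out.dropped)


def test_filter_disjoint_sets_all_kept():
    coll = make_coll(A=[f"a{i}" for i in range(6)], B=[f"b{i}" for i in range(6)])
    out = filter_collection(coll, universe=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
    assert set(out.sets) == {"A", "B"}


def test_filter_exclusion_list():
    coll = make_coll(A=[f"a{i}" for i in range(6)], B=[f"b{i}" for i in range(6)])
    universe = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    out = filter_collection(coll, universe, exclude=["B"])
    assert set(out.sets) == {"A"}


def test_filter_idempotent(small_bundle):
    comp, coll, _, _ = small_bundle
    universe = comp.datasets[0].genes
    once = filter_collection(coll, universe)
    twice = filter_collection(once.collection, universe)
    assert once.sets == twice.sets
    assert twice.dropped == []


def test_filter_prunes_planted_redundant_sets(small_bundle):
    comp, coll, _, _ = small_bundle
    out = filter_collection(coll, comp.datasets[0].genes)
    redundant = [name for name in coll.sets if "R" in name]
    assert redundant
    assert all(name not in out.sets for name in redundant)


# ---------------------------------------------------------------------------
# sample_metric
# ---------------------------------------------------------------------------


def metric_dataset():
    matrix = pd.DataFrame(
        {"D1": [4.0, 1.0, 2.0], "C1": [1.0, 1.0, 2.0], "C2": [3.0, 1.0, 2.0]},
        index=["A", "B", "C"],
    )
    samples = pd.DataFrame(
        {"group": ["disease", "control", "control"], "condition": ["X"] * 3, "tissue": ["LV"] * 3},
        index=pd.Index(["D1", "C1", "C2"], name="sample_id"),
    )
    return ExpressionDataset(dataset_id="M", matrix=matrix, samples=samples)


def test_metric_is_sample_minus_control_mean():
    ranked = sample_metric(metric_dataset(), "D1")
    assert ranked.index[0] == "A"
    assert ranked.loc["A"] == pytest.approx(2.0)
    assert ranked.loc["B"] == pytest.approx(0.0)


def test_metric_matches_explicit_loop(small_bundle):
    comp, _, _, _ = small_bundle
    comparison = comp.comparisons[0]
    ds = comp.dataset(comparison.dataset_id)
    sample = comparison.disease_samples[0]
    ranked = sample_metric(ds, sample, comparison.control_samples)
    for gene in list(ds.genes[:20]):
        expected = ds.matrix.loc[gene, sample] - np.mean(
            [ds.matrix.loc[gene, c] for c in comparison.control_samples]
        )
        assert ranked.loc[gene] == pytest.approx(expected, abs=1e-12)
    assert np.all(np.diff(ranked.to_numpy()) <= 1e-12)


def test_metric_degenerate_warns():
    ds = metric_dataset()
    ds.matrix["D1"] = ds.matrix[["C1", "C2"]].mean(axis=1)
    with pytest.warns(RuntimeWarning, match="degenerate"):
        sample_metric(ds, "D1")


def test_metric_requires_controls():
    with pytest.raises(ValueError, match="control"):
        sample_metric(metric_dataset(), "D1", control_samples=())


# ---------------------------------------------------------------------------
# enrichment_score
# ---------------------------------------------------------------------------


def test_es_top_gene_is_one():
    assert enrichment_score(["a", "b", "c"], [3, 2, 1], {"a"}) == pytest.approx(1.0)


def test_es_bottom_gene_is_minus_one():
    # hand-walked: running sums (-0.5, -1, 0) -> extreme -1
    assert enrichment_score(["a", "b", "c"], [3, 2, 1], {"c"}) == pytest.approx(-1.0)


def test_es_matches_oracle(rng):
    genes = [f"g{i}" for i in range(50)]
    for _ in range(100):
        metrics = np.sort(rng.normal(size=50))[::-1]
        members = set(rng.choice(genes, 8, replace=False))
        es = enrichment_score(genes, metrics, members)
        assert es == pytest.approx(_es_oracle(genes, metrics, members), abs=1e-12)


def test_es_fast_path_matches_walk(rng):
    genes = [f"g{i}" for i in range(60)]
    for _ in range(50):
        metrics = np.sort(rng.normal(size=60))[::-1]
        pos = np.sort(rng.choice(60, 7, replace=False))
        members = {genes[i] for i in pos}
        walk = enrichment_score(genes, metrics, members)
        fast = _es_from_positions(pos[None, :], np.abs(metrics), 60)[0]
        assert fast == pytest.approx(walk, abs=1e-12)


def test_es_antisymmetry(rng):
    genes = [f"g{i}" for i in range(30)]
    metrics = np.sort(rng.normal(size=30))[::-1]
    members = set(rng.choice(genes, 6, replace=False))
    es = enrichment_score(genes, metrics, members)
    flipped = enrichment_score(genes[::-1], (-metrics)[::-1], members)
    assert flipped == pytest.approx(-es, abs=1e-12)


def test_es_guards():
    with pytest.raises(ValueError, match="does not intersect"):
        enrichment_score(["a", "b"], [2, 1], {"z"})
    with pytest.raises(ValueError, match="entire"):
        enrichment_score(["a", "b"], [2, 1], {"a", "b"})


def test_es_zero_metrics_fallback():
    with pytest.warns(RuntimeWarning, match="equal hit increments"):
        es = enrichment_score(["a", "b", "c", "d"], [1.0, 0.0, 0.0, -1.0], {"b", "c"})
    assert -1.0 <= es <= 1.0


# ---------------------------------------------------------------------------
# gene_permutation_p
# ---------------------------------------------------------------------------


def test_p_of_zero_es_is_one():
    assert gene_permutation_p([3.0, 2.0, 1.0], 1, 0.0, n_perm=10, seed=0) == 1.0


def test_p_floor_for_extreme_top_gene(rng):
    # steep metric, single top gene: near the add-one floor
    metrics = np.r_[100.0, np.abs(rng.normal(size=49)) * 0.01]
    genes = [f"g{i}" for i in range(50)]
    es = enrichment_score(genes, metrics, {"g0"})
    p = gene_permutation_p(metrics, 1, es, n_perm=50, seed=1)
    null = _null_es(np.abs(metrics), 1, 50, np.random.default_rng(1))
    positives = int((null > 0).sum())
    extreme = int((np.abs(null[null > 0]) >= abs(es)).sum())
    assert p == pytest.approx((1 + extreme) / (1 + positives))
    assert p <= 3 / (1 + positives)


def test_null_es_mean_zero(rng):
    metrics = np.sort(rng.normal(size=200))[::-1]
    null = _null_es(np.abs(metrics), 15, 1000, rng)
    se = null.std(ddof=1) / np.sqrt(null.size)
    assert abs(null.mean()) < 3 * se + 0.02


def test_sample_positions_distinct_and_sorted(rng):
    for size, total in ((3, 100), (40, 90), (8, 50)):
        pos = _sample_positions(rng, 200, total, size)
        assert pos.shape == (200, size)
        assert np.all(np.diff(pos, axis=1) > 0)
        assert pos.min() >= 0 and pos.max() < total


def test_permutation_p_requires_positive_n_perm():
    with pytest.raises(ValueError):
        gene_permutation_p([1.0, 2.0], 1, 0.5, n_perm=0)


# ---------------------------------------------------------------------------
# compendium-level enrichment
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_enrichment(small_bundle):
    comp, coll, _, _ = small_bundle
    return enrich_compendium(comp, coll, n_perm=100, seed=55)


def test_enrich_covers_every_disease_sample(small_bundle, small_enrichment):
    comp, _, _, _ = small_bundle
    expected = {s for c in comp.comparisons for s in c.disease_samples}
    assert {e.sample_id for e in small_enrichment} == expected


def test_enrichment_tables_valid(small_enrichment):
    for enr in small_enrichment:
        t = enr.table
        assert np.all(np.abs(t["es"]) <= 1.0)
        assert np.all((t["p"] > 0) & (t["p"] <= 1.0))
        sig = t["significant"]
        assert np.all(sig == ((t["p"] < 0.05) & (t["es"] != 0.0)))


def test_planted_pathways_significant_in_member_samples(small_bundle, small_enrichment):
    _, _, _, manifest = small_bundle
    hits = total = 0
    for enr in small_enrichment:
        active = manifest.active_pathways[enr.condition]
        for name, direction in active.items():
            if name in enr.table.index:
                total += 1
                row = enr.table.loc[name]
                hits += bool(row["significant"] and row["direction"] == direction)
    assert total > 40
    assert hits / total > 0.6
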