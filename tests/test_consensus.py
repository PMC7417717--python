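import numpy as np
import pytest

from hfcommons.consensus import (
    condition_dysregulation,
    figure_coords,
    frequent_pathways,
    gene_consensus,
    list_enrichment,
    ora_annotate,
    sharing_profile,
)
from hfcommons.io_formats import GeneSetCollection


def de_from_counts(make_de_result, n_up, n_down, n_comparisons=25, gene="g"):
    """Fabricate one gene's calls across comparisons."""
    results = []
    for i in range(n_comparisons):
        call = "up" if i < n_up else ("down" if i < n_up + n_down else "none")
        results.append(make_de_result(f"cmp{i}", {gene: call}))
    return results


# ---------------------------------------------------------------------------
# gene_consensus
# ---------------------------------------------------------------------------


def test_mixed_direction_frequent_gene(make_de_result):
    # up in 17, down in 6 of 25 -> frequent, direction up
    gc = gene_consensus(de_from_counts(make_de_result, 17, 6))
    row = gc.table.loc["g"]
    assert row["n_de"] == 23 and row["fdeg"] and row["direction"] == "up"


def test_fourteen_of_25_is_not_frequent(make_de_result):
    gc = gene_consensus(de_from_counts(make_de_result, 14, 0), fdeg_min=15)
    assert not gc.table.loc["g", "fdeg"]


def test_all_down_gene(make_de_result):
    gc = gene_consensus(de_from_counts(make_de_result, 0, 25))
    row = gc.table.loc["g"]
    assert row["fdeg"] and row["direction"] == "down" and row["n_down"] == 25


def test_default_threshold_is_sixty_percent_ceiling(make_de_result):
    gc = gene_consensus(de_from_counts(make_de_result, 15, 0))
    assert gc.fdeg_min == 15
    assert gc.table.loc["g", "fdeg"]


def test_direction_tie_broken_by_summed_ratio(make_de_result):
    results = []
    for i in range(4):
        call = "up" if i < 2 else "down"
        results.append(make_de_result(f"c{i}", {"g": call}, ratios={"g": -1.0}))
    gc = gene_consensus(results, fdeg_min=4)
    assert gc.table.loc["g", "direction"] == "down"


def test_duplicate_comparison_ids_rejected(make_de_result):
    results = [make_de_result("c0", {"g": "up"}), make_de_result("c0", {"g": "up"})]
    with pytest.raises(ValueError, match="duplicate"):
        gene_consensus(results)


def test_consensus_order_invariant(make_de_result):
    results = de_from_counts(make_de_result, 10, 5)
    a = gene_consensus(results).table
    b = gene_consensus(results[::-1]).table
    assert a.equals(b)


def test_raising_threshold_shrinks_fdeg_set(make_de_result):
    results = []
    for i in range(10):
        results.append(
            make_de_result(f"c{i}", {"a": "up", "b": "up" if i < 6 else "none"})
        )
    loose = set(gene_consensus(results, fdeg_min=5).fdegs())
    strict = set(gene_consensus(results, fdeg_min=8).fdegs())
    assert strict <= loose
    assert strict == {"a"} and loose == {"a", "b"}


# ---------------------------------------------------------------------------
# sharing_profile
# ---------------------------------------------------------------------------


def test_profile_all_singletons(make_de_result):
    results = [make_de_result("c0", {"a": "up", "b": "down", "c": "none"})]
    profile = sharing_profile(gene_consensus(results, fdeg_min=1))
    assert profile.counts.to_dict() == {1: 2}
    assert profile.n_degs == 2


def test_profile_fraction_above_matches_printed_counts(make_de_result):
    # 242 genes shared by 13 comparisons, 6443 singletons -> 3.6%
    calls_high = {f"h{i}": "up" for i in range(242)}
    calls_low = {f"l{i}": "up" for i in range(6443)}
    results = [make_de_result(f"c{j}", {**calls_high, **({} if j else calls_low)}) for j in range(13)]
    for j in range(13, 25):
        results.append(make_de_result(f"c{j}", {}))
    profile = sharing_profile(gene_consensus(results))
    assert profile.n_degs == 6685
    assert round(100 * profile.fraction_above(12), 1) == 3.6


def test_profile_total_is_deg_count(make_de_result):
    results = de_from_counts(make_de_result, 3, 2, n_comparisons=10)
    profile = sharing_profile(gene_consensus(results, fdeg_min=2))
    assert profile.counts.sum() == profile.n_degs


# ---------------------------------------------------------------------------
# condition / frequency consensus
# ---------------------------------------------------------------------------


def test_condition_strict_majority(make_enrichment):
    # 3 of 5 significant -> flagged; 2 of 4 -> not
    enr5 = [make_enrichment(f"s{i}", {"P": (0.5, 0.01 if i < 3 else 0.5)}, condition="A") for i in range(5)]
    enr4 = [make_enrichment(f"t{i}", {"P": (0.5, 0.01 if i < 2 else 0.5)}, condition="B") for i in range(4)]
    flags = condition_dysregulation(enr5 + enr4)
    assert bool(flags.loc["P", "A"]) is True
    assert bool(flags.loc["P", "B"]) is False


def test_frequent_boundary_249_of_414(make_enrichment):
    for n_sig, expected in ((249, True), (248, False)):
        enr = [
            make_enrichment(f"s{i}", {"P": (0.5, 0.01 if i < n_sig else 0.5)})
            for i in range(414)
        ]
        pc = frequent_pathways(enr, frac=0.6)
        assert bool(pc.table.loc["P", "frequent"]) is expected
        assert pc.table.loc["P", "n_significant"] == n_sig


def test_up_down_tally(make_enrichment):
    enr = [make_enrichment(f"s{i}", {"P": (0.5, 0.01)}) for i in range(6)]
    pc = frequent_pathways(enr)
    row = pc.table.loc["P"]
    assert row["n_up"] == 6 and row["n_down"] == 0
    assert row["n_up"] + row["n_down"] == row["n_significant"]


def test_consensus_conserves_significance_counts(make_enrichment, rng):
    enr = []
    for i in range(40):
        rows = {f"P{j}": (float(rng.normal()), float(rng.random())) for j in range(8)}
        enr.append(make_enrichment(f"s{i}", rows))
    pc = frequent_pathways(enr)
    for pathway in pc.table.index:
        expected = sum(bool(e.table.loc[pathway, "significant"]) for e in enr)
        assert pc.table.loc[pathway, "n_significant"] == expected


# ---------------------------------------------------------------------------
# scatter coordinates
# ---------------------------------------------------------------------------


def test_coords_zero_and_full(make_enrichment):
    enr_null = [make_enrichment(f"s{i}", {"P": (0.5, 0.9)}) for i in range(5)]
    coords = figure_coords(frequent_pathways(enr_null))
    assert coords.loc["P", "x"] == 0.0 and coords.loc["P", "y"] == 0.0
    enr_full = [make_enrichment(f"s{i}", {"P": (0.5, 0.01)}) for i in range(5)]
    coords = figure_coords(frequent_pathways(enr_full))
    assert coords.loc["P", "x"] == 1.0 and coords.loc["P", "y"] == 1.0


def test_coords_x_dominates_abs_y(make_enrichment, rng):
    enr = []
    for i in range(60):
        rows = {f"P{j}": (float(rng.normal()), float(rng.random())) for j in range(10)}
        enr.append(make_enrichment(f"s{i}", rows))
    coords = figure_coords(frequent_pathways(enr))
    assert np.all(coords["x"] >= np.abs(coords["y"]) - 1e-12)


# ---------------------------------------------------------------------------
# flat-list enrichment
# ---------------------------------------------------------------------------


def test_list_enrichment_disjoint_is_one():
    _, p = list_enrichment({"a"}, {"b"}, {"a", "b", "c", "d"})
    assert p == 1.0


def test_list_enrichment_half_universe():
    overlap, p = list_enrichment({"a", "b"}, {"a", "b"}, {"a", "b", "c", "d"})
    assert overlap == 2
    assert p == pytest.approx(1 / 6, abs=1e-12)


def test_list_enrichment_relabel_invariant():
    p1 = list_enrichment({"a", "b"}, {"a", "c"}, {"a", "b", "c", "d", "e"})[1]
    p2 = list_enrichment({"x", "y"}, {"x", "z"}, {"x", "y", "z", "w", "v"})[1]
    assert p1 == p2


def test_list_enrichment_empty_universe():
    with pytest.raises(ValueError):
        list_enrichment({"a"}, {"a"}, set())


def test_ora_extreme_term_significant():
    universe = {f"g{i}" for i in range(1000)}
    term = {f"g{i}" for i in range(10)}
    coll = GeneSetCollection(sets={"T": term, "U": {f"g{i}" for i in range(500, 520)}})
    table = ora_annotate(term, coll, universe)
    assert bool(table.loc["T", "significant"]) is True
    assert table.loc["T", "p"] < 1e-10
    assert bool(table.loc["U", "significant"]) is False


def test_ora_disjoint_query_nothing_significant():
    universe = {f"g{i}" for i in range(100)}
    coll = GeneSetCollection(sets={"T": {f"g{i}" for i in range(10)}})
    table = ora_annotate({f"g{i}" for i in range(50, 60)}, coll, universe)
    assert not table["significant"].any()


def test_ora_matches_list_enrichment(rng):
    universe = {f"g{i}" for i in range(60)}
    coll = GeneSetCollection(
        sets={f"T{j}": set(rng.choice(sorted(universe), 10, replace=False)) for j in range(5)}
    )
    query = set(rng.choice(sorted(universe), 15, replace=False))
    table = ora_annotate(query, coll, universe)
    for term in table.index:
        overlap, p = list_enrichment(query, coll.sets[term], universe)
        assert table.loc[term, "overlap"] == overlap
        assert table.loc[term, "p"] == pytest.approx(p, abs=1e-12)
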