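"""Tier 3: TF -> pathway target over-representation screen.

Every (TF, consensus pathway) pair is tested with a one-sided Fisher exact
test of the TF's targets against the pathway within a common universe,
plus a coverage ratio ``overlap / |pathway & universe|``.  BH adjustment
is applied once over the full pair grid, and an edge passes when
``p_adj < q`` and ``ratio > ratio_cut``.

The universe defaults to (all network target genes) | (all genes of the
screened collection) so that both table margins are drawn from the same
population; it is configurable.  The ratio is pathway coverage rather than
a fraction of the TF's target list, so hub TFs with large target sets can
still pass the gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import RegulatoryNetwork
from .stats_core import ContingencyTable2x2, bh_adjust, fisher_greater

logger = logging.getLogger(__name__)

__all__ = ["TFPathwayResult", "tf_pathway_test", "tf_pathway_screen"]

Q_THRESHOLD = 0.05
RATIO_CUT = 0.2


@dataclass
class TFPathwayResult:
    """Screen output: one row per tested (tf, pathway) pair."""

    table: pd.DataFrame  # columns: tf, pathway, overlap, pathway_size, n_targets, ratio, p, p_adj, pass
    universe_size: int

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["pass"]]

    def degree_summary(self) -> dict:
        """Mean degrees over entities with at least one passing edge."""
        edges = self.passing()
        n_edges = len(edges)
        n_tfs = edges["tf"].nunique()
        n_pathways = edges["pathway"].nunique()
        return {
            "n_edges": n_edges,
            "n_tfs": n_tfs,
            "n_pathways": n_pathways,
            "mean_tfs_per_pathway": n_edges / n_pathways if n_pathways else float("nan"),
            "mean_pathways_per_tf": n_edges / n_tfs if n_tfs else float("nan"),
        }


def tf_pathway_test(tf_targets, pathway_genes, universe) -> tuple:
    """(overlap, ratio, p) for one TF against one pathway within a universe."""
    universe = frozenset(universe)
    pathway = frozenset(pathway_genes) & universe
    if not pathway:
        raise ValueError("pathway has no genes in the universe")
    targets = frozenset(tf_targets) & universe
    a = len(targets & pathway)
    b = len(targets) - a
    c = len(pathway) - a
    d = len(universe) - a - b - c
    p = fisher_greater(ContingencyTable2x2(a, b, c, d))
    return a, a / len(pathway), p


def tf_pathway_screen(
    net: RegulatoryNetwork,
    pathway_names,
    coll,
    q: float = Q_THRESHOLD,
    ratio_cut: float = RATIO_CUT,
    universe=None,
) -> TFPathwayResult:
    """Test every TF against every named pathway of ``coll``.

    ``pathway_names`` is typically the frequent set from the consensus
    tier; ``coll`` any object exposing ``.sets`` (filtered or raw
    collection).  BH is applied jointly across all screened pairs.
    """
    if len(net) == 0:
        raise ValueError("empty regulatory network")
    pathway_names = [p for p in pathway_names]
    if not pathway_names:
        raise ValueError("no pathways to screen")
    missing = [p for p in pathway_names if p not in coll.sets]
    if missing:
        raise ValueError(f"pathways not in collection: {missing[:5]}")
    if universe is None:
        pooled = set(net.targets)
        for genes in coll.sets.values():
            pooled |= genes
        universe = pooled
    universe = frozenset(universe)

    rows = []
    for tf in sorted(net.tf_index):
        targets = net.tf_index[tf]
        targets_in_universe = targets & universe
        for pathway in pathway_names:
            genes = coll.sets[pathway] & universe
            if not genes:
                raise ValueError(f"pathway {pathway} empty within universe")
            overlap, ratio, p = tf_pathway_test(targets, genes, universe)
            rows.append((tf, pathway, overlap, len(genes), len(targets_in_universe), ratio, p))
    table = pd.DataFrame(
        rows, columns=["tf", "pathway", "overlap", "pathway_size", "n_targets", "ratio", "p"]
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["pass"] = (table["p_adj"] < q) & (table["ratio"] > ratio_cut)
    result = TFPathwayResult(table=table, universe_size=len(universe))
    summary = result.degree_summary()
    logger.info(
        "TF screen: %d passing edges between %d TFs and %d pathways",
        summary["n_edges"], summary["n_tfs"], summary["n_pathways"],
    )
    return result
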