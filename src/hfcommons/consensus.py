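"""Cross-comparison and cross-sample consensus summaries (tiers 1 + 2).

Gene level: tally per-comparison up/down calls, flag frequent genes (DE in
at least ``ceil(0.6 * n_comparisons)`` comparisons by default — the 60%
boundary is inclusive) and classify their direction by majority vote, with
ties broken by the sign of the summed average log-ratios.

Pathway level: per-condition dysregulation (significant in a strict
majority of that condition's disease samples) and the pooled frequency
call (significant in more than ``frac`` of all disease samples).  The
scatter coordinates summarise each pathway as ``x = M_up + N_down`` and
``y = M_up - N_down`` where ``M_up``/``N_down`` are the proportions of
samples significantly up/down.

Flat-list enrichment helpers (one-sided Fisher against a universe and BH
over a term collection) cover immune-gene and annotation analyses; no
ontology-hierarchy handling is performed — term sets are taken as given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection
from .stats_core import ContingencyTable2x2, bh_adjust, fisher_greater

logger = logging.getLogger(__name__)

__all__ = [
    "GeneConsensus",
    "SharingProfile",
    "PathwayConsensus",
    "gene_consensus",
    "sharing_profile",
    "condition_dysregulation",
    "frequent_pathways",
    "figure_coords",
    "list_enrichment",
    "ora_annotate",
]

FDEG_FRACTION = 0.6
PATHWAY_FRACTION = 0.6


@dataclass
class GeneConsensus:
    """Per-gene cross-comparison tally.

    ``table`` is indexed by gene with columns ``n_up, n_down, n_de, fdeg,
    direction`` (direction is set for frequent genes only).
    """

    table: pd.DataFrame
    n_comparisons: int
    fdeg_min: int

    def fdegs(self) -> pd.Index:
        return self.table.index[self.table["fdeg"]]


@dataclass
class SharingProfile:
    """Histogram of how many comparisons each DEG is shared by."""

    counts: pd.Series  # index: n_de (>= 1), value: number of genes
    n_degs: int

    def fraction_above(self, k: int) -> float:
        """Fraction of DEGs differentially expressed in more than ``k`` comparisons."""
        if self.n_degs == 0:
            raise ValueError("no DEGs in profile")
        shared = int(self.counts[self.counts.index > k].sum())
        return shared / self.n_degs


@dataclass
class PathwayConsensus:
    """Per-pathway sample-frequency tally.

    ``table`` is indexed by pathway with columns ``n_significant, n_up,
    n_down, frequent``.
    """

    table: pd.DataFrame
    n_samples: int
    frac: float

    def frequent(self) -> pd.Index:
        return self.table.index[self.table["frequent"]]


def gene_consensus(de_results, fdeg_min: int | None = None) -> GeneConsensus:
    """Tally DE calls per gene over comparisons and flag frequent genes."""
    if not de_results:
        raise ValueError("need at least one DE result")
    ids = [r.comparison_id for r in de_results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate comparison ids")
    n_comparisons = len(de_results)
    if fdeg_min is None:
        fdeg_min = math.ceil(FDEG_FRACTION * n_comparisons)
    if fdeg_min > n_comparisons:
        raise ValueError("fdeg_min exceeds the number of comparisons")

    calls = pd.concat(
        [r.table["call"].rename(r.comparison_id) for r in de_results], axis=1, sort=True
    )
    ratios = pd.concat(
        [r.table["avg_log_ratio"].rename(r.comparison_id) for r in de_results], axis=1, sort=True
    )
    n_up = (calls == "up").sum(axis=1).astype(int)
    n_down = (calls == "down").sum(axis=1).astype(int)
    n_de = n_up + n_down
    fdeg = n_de >= fdeg_min

    direction = np.where(n_up > n_down, "up", np.where(n_down > n_up, "down", ""))
    tied = fdeg & (n_up == n_down)
    if tied.any():
        # majority tie: classify by the sign of the summed average log-ratios
        sums = ratios.sum(axis=1, skipna=True)
        direction = np.where(tied, np.where(sums >= 0, "up", "down"), direction)
        logger.info("%d frequent genes with tied direction classified by summed log-ratio", int(tied.sum()))
    direction = np.where(fdeg, direction, "")

    table = pd.DataFrame(
        {"n_up": n_up, "n_down": n_down, "n_de": n_de, "fdeg": fdeg, "direction": direction}
    )
    table.index.name = "gene"
    return GeneConsensus(table=table, n_comparisons=n_comparisons, fdeg_min=int(fdeg_min))


def sharing_profile(gc: GeneConsensus) -> SharingProfile:
    """Exact (n_de -> gene count) histogram over genes DE at least once."""
    n_de = gc.table.loc[gc.table["n_de"] > 0, "n_de"]
    counts = n_de.value_counts().sort_index()
    counts.index.name = "n_comparisons"
    return SharingProfile(counts=counts, n_degs=int(len(n_de)))


def condition_dysregulation(enrichments, frac: float = 0.5) -> pd.DataFrame:
    """Pathway x condition flags: significant in strictly more than ``frac``
    of the condition's disease samples (default: strict majority)."""
    if not enrichments:
        raise ValueError("no enrichment results")
    by_condition: dict = {}
    for enr in enrichments:
        by_condition.setdefault(enr.condition, []).append(enr)
    pathways = sorted({p for enr in enrichments for p in enr.table.index})
    flags = {}
    for condition, group in sorted(by_condition.items()):
        n = len(group)
        if n == 0:
            raise ValueError(f"condition {condition} has zero disease samples")
        sig = pd.Series(0, index=pd.Index(pathways, name="pathway"), dtype=int)
        for enr in group:
            hit = enr.table.index[enr.table["significant"]]
            sig.loc[hit.intersection(sig.index)] += 1
        flags[condition] = sig > frac * n
    return pd.DataFrame(flags)


def frequent_pathways(enrichments, frac: float = PATHWAY_FRACTION) -> PathwayConsensus:
    """Pooled frequency tally: frequent iff significant in strictly more
    than ``frac`` of all disease samples; up/down tallied by ES sign among
    significant samples."""
    if not enrichments:
        raise ValueError("no enrichment results")
    n_samples = len(enrichments)
    pathways = sorted({p for enr in enrichments for p in enr.table.index})
    idx = pd.Index(pathways, name="pathway")
    n_sig = pd.Series(0, index=idx, dtype=int)
    n_up = pd.Series(0, index=idx, dtype=int)
    n_down = pd.Series(0, index=idx, dtype=int)
    for enr in enrichments:
        t = enr.table
        sig = t["significant"]
        up = t.index[sig & (t["es"] > 0)]
        down = t.index[sig & (t["es"] < 0)]
        n_sig.loc[t.index[sig].intersection(idx)] += 1
        n_up.loc[up.intersection(idx)] += 1
        n_down.loc[down.intersection(idx)] += 1
    table = pd.DataFrame(
        {
            "n_significant": n_sig,
            "n_up": n_up,
            "n_down": n_down,
            "frequent": n_sig > frac * n_samples,
        }
    )
    return PathwayConsensus(table=table, n_samples=n_samples, frac=frac)


def figure_coords(pc: PathwayConsensus) -> pd.DataFrame:
    """Per-pathway scatter coordinates ``(M_up + N_down, M_up - N_down)``."""
    m_up = pc.table["n_up"] / pc.n_samples
    n_down = pc.table["n_down"] / pc.n_samples
    return pd.DataFrame({"x": m_up + n_down, "y": m_up - n_down})


def list_enrichment(query, reference, universe) -> tuple:
    """Overlap count and one-sided Fisher p of ``query`` against
    ``reference`` within ``universe``."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query) & universe
    reference = frozenset(reference) & universe
    a = len(query & reference)
    b = len(reference) - a
    c = len(query) - a
    d = len(universe) - a - b - c
    return a, fisher_greater(ContingencyTable2x2(a, b, c, d))


def ora_annotate(query, annotation: GeneSetCollection, universe, q: float = 0.05) -> pd.DataFrame:
    """Flat over-representation analysis of ``query`` against every term.

    Per term: hypergeometric upper-tail p; BH adjustment across terms;
    significant at ``p_adj < q``.
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation collection")
    rows = []
    for term, genes in annotation.sets.items():
        overlap, p = list_enrichment(query, genes, universe)
        rows.append((term, overlap, p))
    table = pd.DataFrame(rows, columns=["term", "overlap", "p"]).set_index("term")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < q
    return table
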