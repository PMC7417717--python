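"""Shared statistical primitives used by every analysis tier.

All functions are pure and operate on plain arrays; validation is strict so
that downstream modules can rely on the documented contracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "PValueVector",
    "rank_descending",
    "fisher_greater",
    "bh_adjust",
    "roc_auc",
    "one_sample_t",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; ``a`` is the in-both cell.

    Layout (rows: in reference set / not; columns: in query set / not)::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table must have positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PValueVector:
    """Parallel (id, p-value) vectors with basic validation."""

    ids: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values must be parallel")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        arr = np.asarray(self.values, dtype=float)
        if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr))):
            raise ValueError("p-values must lie in [0, 1]")

    def adjusted(self) -> "PValueVector":
        return PValueVector(self.ids, tuple(bh_adjust(self.values)))


def rank_descending(values: Sequence[float]) -> np.ndarray:
    """Rank values so that rank 1 is the largest; ties get the average rank."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite (no NaN/inf)")
    return _sps.rankdata(-arr, method="average")


def fisher_greater(table: ContingencyTable2x2) -> float:
    """One-sided (enrichment) Fisher exact p-value.

    Upper tail of the hypergeometric distribution of cell ``a`` given the
    table margins.  Degenerate margins (empty reference or empty query) carry
    no evidence and return 1.0 by convention.
    """
    a, b, c = table.a, table.b, table.c
    if a + b == 0 or a + c == 0:
        return 1.0
    # population = total, successes = reference size (a+b), draws = query size (a+c)
    return float(_sps.hypergeom.sf(a - 1, table.total, a + b, a + c))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-d vectors")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one positive and one negative label")
    ranks = _sps.rankdata(s, method="average")
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def one_sample_t(null_values: Sequence[float], observed: float) -> float:
    """One-sided p-value that the null-distribution mean lies below ``observed``.

    Student one-sample t-test of ``null_values`` against the fixed point
    ``observed`` with alternative "mean < observed".
    """
    x = np.asarray(null_values, dtype=float)
    if x.size < 3:
        raise ValueError("one_sample_t needs at least 3 null values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("null values have zero variance")
    res = _sps.ttest_1samp(x, popmean=float(observed), alternative="less")
    return float(res.pvalue)
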