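"""Readers/writers and validated containers for every external format.

Formats (all UTF-8, tab-separated):

* expression matrix  — gene-id first column, sample ids in the header;
* sample sheet       — columns ``sample_id, group, condition, tissue,
  dataset_id`` with ``group`` in ``{disease, control}``;
* gene sets          — GMT (one set per line: name, description, genes...);
* regulatory network — two-column edge list (tf, target), extra columns
  ignored, no header;
* result tables      — plain TSV with a header row.

Matrices are assumed already normalised on the log2 scale; no normalisation
is performed here.  Gene identifiers are treated as case-sensitive symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "Comparison",
    "ExpressionCompendium",
    "GeneSetCollection",
    "RegulatoryNetwork",
    "read_expression",
    "write_expression",
    "read_compendium",
    "write_compendium",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "condition", "tissue", "dataset_id")
GROUPS = ("disease", "control")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """One dataset: a log2 gene x sample matrix plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``group`` (disease or
    control), ``condition`` and ``tissue``.
    """

    dataset_id: str
    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.dataset_id:
            raise ValueError("dataset_id must be non-empty")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        for col in ("group", "condition", "tissue"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        matrix_ids = set(map(str, self.matrix.columns))
        sheet_ids = set(map(str, self.samples.index))
        if matrix_ids != sheet_ids:
            missing = sorted(matrix_ids - sheet_ids) + sorted(sheet_ids - matrix_ids)
            raise ValueError(f"unknown sample id in sheet/matrix: {missing[:5]}")
        bad = set(self.samples["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"sample group must be one of {GROUPS}, got {sorted(bad)}")
        if not self.disease_samples:
            raise ValueError("no disease samples")
        if not self.control_samples:
            raise ValueError("no control samples")
        values = self.matrix.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        # keep metadata rows aligned with matrix column order
        self.samples = self.samples.loc[list(self.matrix.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def disease_samples(self) -> tuple:
        return tuple(self.samples.index[self.samples["group"] == "disease"])

    @property
    def control_samples(self) -> tuple:
        return tuple(self.samples.index[self.samples["group"] == "control"])

    @property
    def condition(self) -> str:
        labels = sorted(set(self.samples.loc[list(self.disease_samples), "condition"]))
        return "+".join(labels)

    @property
    def tissue(self) -> str:
        labels = sorted(set(self.samples["tissue"]))
        return "+".join(labels)


@dataclass(frozen=True)
class Comparison:
    """One (dataset x condition x tissue) disease-vs-control stratum."""

    comparison_id: str
    dataset_id: str
    condition: str
    tissue: str
    disease_samples: tuple
    control_samples: tuple


@dataclass
class ExpressionCompendium:
    """Ordered collection of datasets plus derived comparison strata."""

    datasets: list
    comparisons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.comparisons:
            self.comparisons = build_comparisons(self.datasets)
        self.validate()

    def validate(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate dataset ids")
        by_id = {d.dataset_id: d for d in self.datasets}
        strata = set()
        for cmp_ in self.comparisons:
            ds = by_id.get(cmp_.dataset_id)
            if ds is None:
                raise ValueError(f"comparison references unknown dataset {cmp_.dataset_id}")
            known = set(ds.samples.index)
            for sid in tuple(cmp_.disease_samples) + tuple(cmp_.control_samples):
                if sid not in known:
                    raise ValueError(f"comparison {cmp_.comparison_id} references unknown sample {sid}")
            strata.add((cmp_.dataset_id, cmp_.condition, cmp_.tissue))
        if len(strata) != len(self.comparisons):
            raise ValueError("comparisons do not map 1:1 onto (dataset, condition, tissue) strata")

    def dataset(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    @property
    def n_disease_samples(self) -> int:
        return sum(len(d.disease_samples) for d in self.datasets)


def build_comparisons(datasets: Sequence[ExpressionDataset]) -> list:
    """Derive one comparison per (dataset, condition, tissue) disease stratum.

    Controls are matched on tissue within the dataset; when a tissue has no
    dedicated controls the dataset's full control group is used.
    """
    comparisons = []
    for ds in datasets:
        meta = ds.samples
        disease = meta[meta["group"] == "disease"]
        controls = meta[meta["group"] == "control"]
        for (condition, tissue), grp in disease.groupby(["condition", "tissue"], sort=True):
            ctrl = controls[controls["tissue"] == tissue]
            if ctrl.empty:
                ctrl = controls
            comparisons.append(
                Comparison(
                    comparison_id=f"{ds.dataset_id}|{condition}|{tissue}",
                    dataset_id=ds.dataset_id,
                    condition=str(condition),
                    tissue=str(tissue),
                    disease_samples=tuple(grp.index),
                    control_samples=tuple(ctrl.index),
                )
            )
    return comparisons


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. curated pathways) with provenance."""

    sets: dict
    provenance: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            if not name:
                raise ValueError("gene set names must be non-empty")
            genes = frozenset(str(g) for g in genes)
            if any(g == "" for g in genes):
                raise ValueError(f"set {name!r} contains an empty gene symbol")
            clean[str(name)] = genes
        self.sets = clean

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets


@dataclass
class RegulatoryNetwork:
    """Deduplicated TF -> target edge set with a per-TF index."""

    edges: frozenset
    tf_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = frozenset((str(t), str(g)) for t, g in self.edges)
        index: dict = {}
        for tf, target in self.edges:
            index.setdefault(tf, set()).add(target)
        self.tf_index = {tf: frozenset(ts) for tf, ts in index.items()}

    @property
    def tfs(self) -> frozenset:
        return frozenset(self.tf_index)

    @property
    def targets(self) -> frozenset:
        out: set = set()
        for ts in self.tf_index.values():
            out |= ts
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def _read_matrix(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    try:
        mat = mat.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix {path}: {exc}") from None
    if mat.index.duplicated().any():
        n = int(mat.index.duplicated().sum())
        logger.info("averaging %d duplicated gene rows in %s", n, path)
        mat = mat.groupby(level=0, sort=False).mean()
    return mat


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise ValueError(f"sample sheet {path} missing required column {col!r}")
    for col in ("condition", "tissue", "dataset_id"):
        if col not in sheet.columns:
            sheet[col] = ""
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample_id rows in sheet {path}")
    return sheet.set_index("sample_id")


def read_expression(matrix_path, sample_sheet_path, dataset_id: str | None = None) -> ExpressionDataset:
    """Load one dataset from a matrix TSV and its sample sheet.

    Duplicate gene rows are averaged; row and column order are otherwise
    preserved.  The sheet may cover several datasets, in which case
    ``dataset_id`` selects the relevant rows.
    """
    mat = _read_matrix(matrix_path)
    sheet = read_sample_sheet(sample_sheet_path)
    if dataset_id is None:
        # multi-dataset sheet: fall back to the matrix file stem as dataset id
        ids = set(sheet["dataset_id"]) - {""}
        stem = Path(str(matrix_path)).stem
        if len(ids) > 1 and stem in ids:
            dataset_id = stem
    if dataset_id is not None and (sheet["dataset_id"] != "").any():
        sheet = sheet[sheet["dataset_id"] == dataset_id]
    missing = [s for s in mat.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"unknown sample id (matrix column not in sheet): {missing[:5]}")
    extra = [s for s in sheet.index if s not in set(mat.columns)]
    if extra:
        raise ValueError(f"unknown sample id in sheet (no matrix column): {extra[:5]}")
    if dataset_id is None:
        ids = set(sheet["dataset_id"]) - {""}
        dataset_id = ids.pop() if len(ids) == 1 else Path(str(matrix_path)).stem
    return ExpressionDataset(dataset_id=dataset_id, matrix=mat, samples=sheet[["group", "condition", "tissue"]])


def write_expression(ds: ExpressionDataset, matrix_path, sheet_path=None) -> None:
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    ds.matrix.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.10g")
    if sheet_path is not None:
        write_sample_sheet([ds], sheet_path)


def write_sample_sheet(datasets: Sequence[ExpressionDataset], path) -> None:
    rows = []
    for ds in datasets:
        for sid, row in ds.samples.iterrows():
            rows.append(
                {
                    "sample_id": sid,
                    "group": row["group"],
                    "condition": row["condition"],
                    "tissue": row["tissue"],
                    "dataset_id": ds.dataset_id,
                }
            )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=list(SAMPLE_SHEET_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_compendium(sample_sheet_path, matrix_dir) -> ExpressionCompendium:
    """Load every dataset listed in a multi-dataset sample sheet.

    The matrix for dataset ``X`` is expected at ``<matrix_dir>/X.tsv``.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    if (sheet["dataset_id"] == "").any():
        raise ValueError("compendium sample sheet requires a dataset_id for every sample")
    datasets = []
    for dataset_id in pd.unique(sheet["dataset_id"]):
        matrix_path = Path(matrix_dir) / f"{dataset_id}.tsv"
        datasets.append(read_expression(matrix_path, sample_sheet_path, dataset_id=dataset_id))
    return ExpressionCompendium(datasets=datasets)


def write_compendium(comp: ExpressionCompendium, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in comp.datasets:
        write_expression(ds, outdir / f"{ds.dataset_id}.tsv")
    write_sample_sheet(comp.datasets, outdir / "samples.tsv")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Parse an MSigDB-dialect GMT file (name, description, genes...)."""
    sets: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name in coll.sets:
            genes = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------


def read_network(path) -> RegulatoryNetwork:
    """Parse a two-column (tf, target) edge list; extra columns are ignored."""
    edges = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f for f in line.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            edges.add((fields[0], fields[1]))
    net = RegulatoryNetwork(edges=frozenset(edges))
    logger.info(
        "loaded network %s: %d edges, %d TFs, %d targets",
        path, len(net), len(net.tfs), len(net.targets),
    )
    return net


def write_network(net: RegulatoryNetwork, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for tf, target in sorted(net.edges):
            fh.write(f"{tf}\t{target}\n")
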