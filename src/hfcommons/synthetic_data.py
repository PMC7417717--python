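"""Planted-signal compendium generator for benchmarking the three tiers.

The generator emulates the structure of a multi-cohort case/control
compendium: a fixed number of aetiology conditions, a fixed number of
(dataset x condition x tissue) comparisons with unbalanced group sizes, a
shared gene universe with per-dataset missingness, curated-style gene sets
(including deliberately redundant near-duplicates for the overlap filter to
prune) and a TF -> target edge list with planted TF -> pathway couplings.

Planted effects, all on the log2 scale:

* frequent genes  — ``n_fdeg`` genes receive a per-gene fixed-sign shift of
  ``fdeg_effect`` in every comparison of each condition where they are
  active (active per condition with probability ``fdeg_condition_prob``);
* pathways        — each condition activates ``n_active_pathways_per_condition``
  gene sets whose members are shifted by ``pathway_effect`` with a sign
  drawn per (pathway, condition); ``n_core_pathways`` of these are shared
  by every condition so that a globally frequent pathway signal exists;
* TF couplings    — a subset of TFs target a ``tf_pathway_coverage``
  fraction of one core pathway each, on top of random decoy targets.

Every planted fact is recorded in a :class:`TruthManifest` for recovery
testing, including, per gene, the number of comparisons in which it carries
a non-zero net planted shift (frequent-gene recovery must be judged against
this count: members of always-active core pathways are genuinely shifted in
every comparison, not false positives).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionCompendium,
    ExpressionDataset,
    GeneSetCollection,
    RegulatoryNetwork,
    write_compendium,
    write_gmt,
    write_network,
)

__all__ = ["GeneratorConfig", "TruthManifest", "generate_compendium", "generate_null_comparison", "write_synthetic_outputs"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic compendium; defaults are comfortably detectable."""

    n_conditions: int = 11
    n_comparisons: int = 25
    n_genes: int = 2000
    n_disease_range: tuple = (4, 20)
    n_control_range: tuple = (4, 16)
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    n_fdeg: int = 100
    fdeg_effect: float = 1.5
    fdeg_condition_prob: float = 0.9
    n_pathways: int = 100
    pathway_size_range: tuple = (10, 50)
    n_active_pathways_per_condition: int = 15
    n_core_pathways: int = 10
    pathway_effect: float = 1.0
    n_redundant_pathways: int = 5
    n_tfs: int = 50
    n_linked_tfs: int = 20
    tf_pathway_coverage: float = 0.3
    tf_random_targets: int = 30
    missing_frac: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_conditions": self.n_conditions,
            "n_comparisons": self.n_comparisons,
            "n_genes": self.n_genes,
            "n_pathways": self.n_pathways,
            "n_tfs": self.n_tfs,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_fdeg", "n_core_pathways", "n_redundant_pathways", "n_linked_tfs", "tf_random_targets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fdeg_condition_prob", "tf_pathway_coverage", "missing_frac"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.missing_frac >= 0.5:
            raise ValueError("missing_frac must stay below 0.5")
        lo, hi = self.pathway_size_range
        if not (5 <= lo <= hi <= 300):
            raise ValueError("pathway sizes must stay within the (5, 300) analysis window")
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds gene count")
        if self.n_fdeg > self.n_genes:
            raise ValueError("n_fdeg exceeds gene count")
        if self.n_core_pathways * hi + self.n_fdeg > self.n_genes:
            raise ValueError("core pathways and frequent genes cannot be drawn disjointly")
        if self.n_core_pathways + self.n_redundant_pathways > self.n_pathways:
            raise ValueError("core + redundant pathways exceed n_pathways")
        if self.n_active_pathways_per_condition > self.n_pathways - self.n_redundant_pathways:
            raise ValueError("not enough pathways to activate per condition")
        if self.n_active_pathways_per_condition < self.n_core_pathways:
            raise ValueError("n_active_pathways_per_condition must cover the core pathways")
        if self.n_linked_tfs > self.n_tfs:
            raise ValueError("n_linked_tfs exceeds n_tfs")
        for name in ("n_disease_range", "n_control_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be an increasing pair of positive counts")

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        clean = {}
        for key, value in data.items():
            if key.endswith("_range") or key == "pathway_size_range":
                value = tuple(value)
            clean[key] = value
        return cls(**clean)


@dataclass
class TruthManifest:
    """Ground truth of every planted effect, for recovery scoring."""

    fdeg_genes: dict
    active_pathways: dict
    tf_pathway_links: set
    frequent_pathways: set
    gene_shift_counts: dict
    n_comparisons: int

    def frequent_genes(self, min_comparisons: int) -> set:
        """Genes carrying a non-zero planted shift in >= ``min_comparisons``."""
        return {g for g, c in self.gene_shift_counts.items() if c >= min_comparisons}

    def to_json(self, path) -> None:
        payload = {
            "fdeg_genes": self.fdeg_genes,
            "active_pathways": self.active_pathways,
            "tf_pathway_links": sorted(list(e) for e in self.tf_pathway_links),
            "frequent_pathways": sorted(self.frequent_pathways),
            "gene_shift_counts": self.gene_shift_counts,
            "n_comparisons": self.n_comparisons,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            fdeg_genes=payload["fdeg_genes"],
            active_pathways=payload["active_pathways"],
            tf_pathway_links={tuple(e) for e in payload["tf_pathway_links"]},
            frequent_pathways=set(payload["frequent_pathways"]),
            gene_shift_counts={g: int(c) for g, c in payload["gene_shift_counts"].items()},
            n_comparisons=int(payload["n_comparisons"]),
        )


def _sign_label(sign: float) -> str:
    return "up" if sign > 0 else "down"


def generate_compendium(cfg: GeneratorConfig):
    """Generate ``(compendium, gene sets, network, truth manifest)`` from ``cfg``.

    Fully reproducible from ``cfg.seed``: identical configs produce
    byte-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    conditions = [f"COND{j:02d}" for j in range(cfg.n_conditions)]
    comparison_conditions = [conditions[i % cfg.n_conditions] for i in range(cfg.n_comparisons)]

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)

    # --- frequent-gene planting -------------------------------------------
    fdeg_idx = np.sort(rng.choice(cfg.n_genes, cfg.n_fdeg, replace=False))
    fdeg_sign = rng.choice(np.array([1.0, -1.0]), cfg.n_fdeg)
    fdeg_active = rng.random((cfg.n_fdeg, cfg.n_conditions)) < cfg.fdeg_condition_prob

    # --- pathway membership ------------------------------------------------
    lo, hi = cfg.pathway_size_range
    n_regular = cfg.n_pathways - cfg.n_redundant_pathways
    regular_names = [f"SET{i:03d}" for i in range(n_regular)]
    core_names = regular_names[: cfg.n_core_pathways]
    sizes = rng.integers(lo, hi + 1, n_regular)

    membership: dict = {}
    non_fdeg_pool = np.setdiff1d(np.arange(cfg.n_genes), fdeg_idx)
    rng.shuffle(non_fdeg_pool)
    offset = 0
    for name, size in zip(core_names, sizes[: cfg.n_core_pathways]):
        membership[name] = np.sort(non_fdeg_pool[offset : offset + size])
        offset += size
    for name, size in zip(regular_names[cfg.n_core_pathways :], sizes[cfg.n_core_pathways :]):
        membership[name] = np.sort(rng.choice(cfg.n_genes, size, replace=False))

    non_core_names = regular_names[cfg.n_core_pathways :]
    redundant_sources = (
        rng.choice(np.array(non_core_names), cfg.n_redundant_pathways, replace=False)
        if cfg.n_redundant_pathways
        else np.array([], dtype=object)
    )
    for k, source in enumerate(redundant_sources):
        member = membership[str(source)]
        sub = max(5, int(math.ceil(0.9 * member.size)))
        membership[f"{source}R{k}"] = np.sort(rng.choice(member, sub, replace=False))

    collection = GeneSetCollection(
        sets={name: frozenset(genes[idx]) for name, idx in membership.items()},
        provenance="synthetic",
    )

    # --- per-condition pathway activity ------------------------------------
    active_pathways: dict = {}
    pathway_sign: dict = {}
    extra = cfg.n_active_pathways_per_condition - cfg.n_core_pathways
    for cond in conditions:
        chosen = list(core_names)
        if extra and non_core_names:
            chosen += list(rng.choice(np.array(non_core_names), min(extra, len(non_core_names)), replace=False))
        signs = rng.choice(np.array([1.0, -1.0]), len(chosen))
        active_pathways[cond] = dict(zip(chosen, signs))
        for name, s in zip(chosen, signs):
            pathway_sign[(name, cond)] = s

    # --- regulatory network -------------------------------------------------
    tf_names = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    edges: set = set()
    tf_pathway_links: set = set()
    n_linked = cfg.n_linked_tfs if core_names else 0
    for i, tf in enumerate(tf_names):
        targets = set(genes[rng.choice(cfg.n_genes, cfg.tf_random_targets, replace=False)])
        if i < n_linked:
            pathway = core_names[i % len(core_names)]
            member = membership[pathway]
            k = max(1, int(math.ceil(cfg.tf_pathway_coverage * member.size)))
            targets |= set(genes[rng.choice(member, k, replace=False)])
            tf_pathway_links.add((tf, pathway))
        edges |= {(tf, g) for g in targets}
    network = RegulatoryNetwork(edges=frozenset(edges))

    # --- expression matrices -------------------------------------------------
    shift_counts = np.zeros(cfg.n_genes, dtype=int)
    lo_d, hi_d = cfg.n_disease_range
    lo_c, hi_c = cfg.n_control_range
    datasets = []
    for i, cond in enumerate(comparison_conditions):
        ds_id = f"DS{i:02d}"
        cond_j = conditions.index(cond)
        present = rng.random(cfg.n_genes) >= cfg.missing_frac
        n_d = int(rng.integers(lo_d, hi_d + 1))
        n_c = int(rng.integers(lo_c, hi_c + 1))

        shift = np.zeros(cfg.n_genes)
        active_f = fdeg_idx[fdeg_active[:, cond_j]]
        shift[active_f] += fdeg_sign[fdeg_active[:, cond_j]] * cfg.fdeg_effect
        for name, sign in active_pathways[cond].items():
            shift[membership[name]] += sign * cfg.pathway_effect
        shift_counts += ((shift != 0.0) & present).astype(int)

        disease = mu[:, None] + shift[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_d))
        control = mu[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_c))
        sample_ids = [f"{ds_id}_D{k:02d}" for k in range(n_d)] + [f"{ds_id}_C{k:02d}" for k in range(n_c)]
        matrix = pd.DataFrame(
            np.hstack([disease, control])[present], index=genes[present], columns=sample_ids
        )
        samples = pd.DataFrame(
            {
                "group": ["disease"] * n_d + ["control"] * n_c,
                "condition": [cond] * (n_d + n_c),
                "tissue": ["LV"] * (n_d + n_c),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        datasets.append(ExpressionDataset(dataset_id=ds_id, matrix=matrix, samples=samples))

    compendium = ExpressionCompendium(datasets=datasets)

    manifest = TruthManifest(
        fdeg_genes={
            str(genes[fdeg_idx[k]]): {
                "direction": _sign_label(fdeg_sign[k]),
                "active_conditions": [conditions[j] for j in range(cfg.n_conditions) if fdeg_active[k, j]],
            }
            for k in range(cfg.n_fdeg)
        },
        active_pathways={
            cond: {name: _sign_label(sign) for name, sign in chosen.items()}
            for cond, chosen in active_pathways.items()
        },
        tf_pathway_links=tf_pathway_links,
        frequent_pathways=set(core_names),
        gene_shift_counts={str(genes[i]): int(c) for i, c in enumerate(shift_counts) if c > 0},
        n_comparisons=cfg.n_comparisons,
    )
    return compendium, collection, network, manifest


def generate_null_comparison(n_genes: int, n_disease: int, n_control: int, seed: int) -> ExpressionDataset:
    """Pure-noise single-comparison dataset for calibration tests."""
    if min(n_genes, n_disease, n_control) <= 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    mu = rng.normal(8.0, 2.0, n_genes)
    values = mu[:, None] + rng.normal(0.0, 0.5, (n_genes, n_disease + n_control))
    sample_ids = [f"NULL_D{k:02d}" for k in range(n_disease)] + [f"NULL_C{k:02d}" for k in range(n_control)]
    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "group": ["disease"] * n_disease + ["control"] * n_control,
            "condition": ["NULL"] * (n_disease + n_control),
            "tissue": ["LV"] * (n_disease + n_control),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(dataset_id="NULL", matrix=matrix, samples=samples)


def write_synthetic_outputs(outdir, compendium, collection, network, manifest) -> None:
    """Write matrices, sample sheet, GMT, edge list and manifest JSON."""
    outdir = Path(outdir)
    write_compendium(compendium, outdir)
    write_gmt(collection, outdir / "sets.gmt")
    write_network(network, outdir / "network.tsv")
    manifest.to_json(outdir / "manifest.json")
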