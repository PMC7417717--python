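"""End-to-end orchestration: inputs -> tier 1 -> consensus -> tier 2 ->
pathway consensus -> tier 3 -> classifier, from a single config.

Every stage writes a plain TSV/JSON checkpoint into the output directory,
sufficient to recompute downstream stages without re-running upstream.  A
run manifest records the config hash, per-stage seeds and row counts.
Reruns with an identical config are byte-identical: the one global seed
fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, classifier_eval, consensus, gsea_prerank, rankprod_de, tf_pathway
from .io_formats import read_compendium, read_gmt, read_network
from .synthetic_data import GeneratorConfig, generate_compendium, write_synthetic_outputs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds, permutation counts and seeds for one run."""

    # inputs: either a synthetic generator config, or paths to real inputs
    generator: dict | None = None
    sample_sheet: str | None = None
    matrix_dir: str | None = None
    gmt: str | None = None
    network: str | None = None

    # thresholds
    pfp_threshold: float = 0.05
    fdeg_fraction: float = 0.6
    condition_fraction: float = 0.5
    pathway_fraction: float = 0.6
    gsea_alpha: float = 0.05
    min_set_size: int = 5
    max_set_size: int = 300
    overlap_cut: float = 0.8
    tf_q: float = 0.05
    ratio_cut: float = 0.2
    exclude_pathways: list = field(default_factory=list)

    # permutation / repeat counts
    rankprod_n_perm: int = 100
    gsea_n_perm: int = 1000
    classifier_folds: int = 10
    classifier_trees: int = 500
    classifier_repeats: int = 50

    seed: int = 7

    def validate(self) -> None:
        fractions = {
            "pfp_threshold": self.pfp_threshold,
            "fdeg_fraction": self.fdeg_fraction,
            "condition_fraction": self.condition_fraction,
            "pathway_fraction": self.pathway_fraction,
            "gsea_alpha": self.gsea_alpha,
            "overlap_cut": self.overlap_cut,
            "tf_q": self.tf_q,
            "ratio_cut": self.ratio_cut,
        }
        for name, value in fractions.items():
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")
        counts = {
            "min_set_size": self.min_set_size,
            "max_set_size": self.max_set_size,
            "rankprod_n_perm": self.rankprod_n_perm,
            "gsea_n_perm": self.gsea_n_perm,
            "classifier_folds": self.classifier_folds,
            "classifier_trees": self.classifier_trees,
            "classifier_repeats": self.classifier_repeats,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.generator is None and not (self.sample_sheet and self.matrix_dir and self.gmt and self.network):
            raise ValueError("config needs either a generator block or all four input paths")
        if self.generator is not None:
            GeneratorConfig.from_dict(self.generator).validate()

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int) -> list:
    return [int(child.generate_state(1)[0]) for child in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed, 4)  # synth, rankprod, gsea, classifier
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stage_seeds": seeds,
        "stages": {},
    }

    def record(stage: str, path, n_rows: int, **extra) -> None:
        manifest["stages"][stage] = {"output": str(path.name), "rows": int(n_rows), **extra}
        logger.info("stage %s: %d rows -> %s", stage, n_rows, path.name)

    # --- stage 0: inputs ----------------------------------------------------
    try:
        if cfg.generator is not None:
            gen_cfg = dataclasses.replace(GeneratorConfig.from_dict(cfg.generator), seed=seeds[0])
            comp, coll, net, truth = generate_compendium(gen_cfg)
            inputs_dir = outdir / "inputs"
            write_synthetic_outputs(inputs_dir, comp, coll, net, truth)
            record("inputs", inputs_dir / "samples.tsv", sum(len(d.samples) for d in comp.datasets),
                   datasets=len(comp.datasets), comparisons=len(comp.comparisons))
        else:
            comp = read_compendium(cfg.sample_sheet, cfg.matrix_dir)
            coll = read_gmt(cfg.gmt)
            net = read_network(cfg.network)
            record("inputs", Path(cfg.sample_sheet), sum(len(d.samples) for d in comp.datasets),
                   datasets=len(comp.datasets), comparisons=len(comp.comparisons))
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    # --- stage 1: rank-product DE -------------------------------------------
    def _rankprod():
        results = rankprod_de.run_compendium(
            comp, n_perm=cfg.rankprod_n_perm, seed=seeds[1], pfp_threshold=cfg.pfp_threshold
        )
        frames = []
        for r in results:
            t = r.table.reset_index(names="gene")
            t.insert(0, "comparison_id", r.comparison_id)
            frames.append(t)
        import pandas as pd

        de_path = outdir / "de_results.tsv"
        pd.concat(frames, ignore_index=True).to_csv(de_path, sep="\t", index=False, float_format="%.8g")
        record("rankprod", de_path, sum(len(r.table) for r in results),
               degs=int(sum(len(r.degs()) for r in results)))
        return results

    de_results = stage("rankprod", _rankprod)

    # --- stage 2: gene consensus ---------------------------------------------
    def _gene_consensus():
        fdeg_min = math.ceil(cfg.fdeg_fraction * len(de_results))
        gc = consensus.gene_consensus(de_results, fdeg_min=fdeg_min)
        path = outdir / "gene_consensus.tsv"
        gc.table.to_csv(path, sep="\t", float_format="%.8g")
        profile = consensus.sharing_profile(gc)
        profile.counts.rename("n_genes").to_csv(outdir / "sharing_profile.tsv", sep="\t")
        record("gene_consensus", path, len(gc.table), fdegs=int(gc.table["fdeg"].sum()))
        return gc

    gc = stage("gene_consensus", _gene_consensus)

    # --- stage 3: per-sample enrichment --------------------------------------
    def _gsea():
        enr = gsea_prerank.enrich_compendium(
            comp, coll, n_perm=cfg.gsea_n_perm, seed=seeds[2],
            min_size=cfg.min_set_size, max_size=cfg.max_set_size,
            overlap_cut=cfg.overlap_cut, exclude=cfg.exclude_pathways, alpha=cfg.gsea_alpha,
        )
        frame = gsea_prerank.enrichment_to_frame(enr)
        path = outdir / "sample_enrichment.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
        record("gsea", path, len(frame), samples=len(enr))
        return enr

    enrichments = stage("gsea", _gsea)

    # --- stage 4: pathway consensus -------------------------------------------
    def _pathway_consensus():
        flags = consensus.condition_dysregulation(enrichments, frac=cfg.condition_fraction)
        flags.to_csv(outdir / "condition_dysregulation.tsv", sep="\t", index_label="pathway")
        pc = consensus.frequent_pathways(enrichments, frac=cfg.pathway_fraction)
        path = outdir / "pathway_consensus.tsv"
        pc.table.to_csv(path, sep="\t")
        consensus.figure_coords(pc).to_csv(outdir / "pathway_coords.tsv", sep="\t", float_format="%.8g")
        record("pathway_consensus", path, len(pc.table), frequent=int(pc.table["frequent"].sum()))
        return pc

    pc = stage("pathway_consensus", _pathway_consensus)

    # --- stage 5: TF screen ----------------------------------------------------
    def _tf_screen():
        frequent = list(pc.frequent())
        path = outdir / "tf_edges.tsv"
        if not frequent:
            path.write_text("tf\tpathway\toverlap\tpathway_size\tn_targets\tratio\tp\tp_adj\tpass\n")
            record("tf_screen", path, 0, note="no frequent pathways")
            return None
        screen = tf_pathway.tf_pathway_screen(net, frequent, coll, q=cfg.tf_q, ratio_cut=cfg.ratio_cut)
        screen.table.to_csv(path, sep="\t", index=False, float_format="%.8g")
        record("tf_screen", path, len(screen.table), **screen.degree_summary())
        return screen

    stage("tf_screen", _tf_screen)

    # --- stage 6: classifier ----------------------------------------------------
    def _classifier():
        fdegs = list(gc.fdegs())
        path = outdir / "classifier.json"
        pool = classifier_eval.detected_everywhere(comp)
        usable = [g for g in fdegs if g in set(pool)]
        min_class = min(
            sum(len(d.disease_samples) for d in comp.datasets),
            sum(len(d.control_samples) for d in comp.datasets),
        )
        if len(usable) < 2 or min_class < cfg.classifier_folds:
            payload = {"skipped": True, "reason": "too few usable frequent genes or samples"}
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
            record("classifier", path, 0, skipped=True)
            return None
        report = classifier_eval.evaluate_signature(
            comp, usable, n_folds=cfg.classifier_folds, n_trees=cfg.classifier_trees,
            n_repeats=cfg.classifier_repeats, seed=seeds[3],
        )
        path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
        record("classifier", path, len(report.features_used),
               auc=report.auc, null_mean_auc=report.null_mean)
        return report

    stage("classifier", _classifier)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
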