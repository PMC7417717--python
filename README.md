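# hfcommons

Three-tiered integrative analysis of multi-cohort case/control
transcriptomics, built around a shared question: which genes, pathways and
upstream regulators are dysregulated *consistently* across many disease
aetiologies?

1. **Gene tier** — per-comparison rank-product differential expression
   (all disease×control sample pairs, geometric-mean ranks, sample-shuffle
   permutation p/pfp), then a cross-comparison frequency consensus that
   flags genes differentially expressed in ≥60% of comparisons and
   classifies their direction.
2. **Pathway tier** — per-disease-sample pre-ranked gene set enrichment
   (sample-minus-control-mean metric, weighted-KS enrichment score,
   gene-permutation nominal p) over a size- and redundancy-filtered GMT
   collection, then per-condition (strict majority) and pooled (>60% of all
   disease samples) frequency consensus.
3. **Network tier** — every (TF, consensus pathway) pair screened for
   target over-representation with a one-sided Fisher exact test, BH
   adjustment over the full grid and a pathway-coverage ratio gate.

Support: strict TSV/GMT/edge-list I/O, a planted-signal synthetic
compendium generator with a ground-truth manifest for recovery testing, a
random-forest signature evaluator (pooled out-of-fold CV AUC vs a
random-gene baseline), and a one-config pipeline runner.

## Command line

```bash
# generate a synthetic compendium (matrices, sample sheet, GMT, edge list,
# truth manifest) into a directory
hfcommons synth --outdir data/ --seed 7

# tier 1 for one dataset (all of its comparison strata)
hfcommons rankprod --matrix data/DS00.tsv --samples data/samples.tsv \
    --n-perm 100 --seed 7 --out de.tsv

# tier 2 for one dataset
hfcommons gsea --matrix data/DS00.tsv --samples data/samples.tsv \
    --gmt data/sets.gmt --n-perm 1000 --seed 7 --out enr.tsv

# signature evaluation
hfcommons classify --matrix-dir data/ --samples data/samples.tsv \
    --genes fdeg.txt --folds 10 --repeats 1000 --seed 7 --out report.json

# the whole pipeline from one YAML config
hfcommons run --config cfg.yaml --outdir results/
```

A minimal pipeline config (`cfg.yaml`) uses the synthetic generator:

```yaml
generator:
  n_genes: 2000
  n_comparisons: 25
rankprod_n_perm: 100
gsea_n_perm: 1000
seed: 7
```

Real inputs are supplied instead of `generator:` via `sample_sheet`,
`matrix_dir`, `gmt` and `network` paths; all thresholds (pfp 0.05, FDEG
fraction 0.6, per-condition fraction 0.5, pathway fraction 0.6, GSEA p
0.05, set-size window [5, 300], overlap 0.8, TF q 0.05, ratio 0.2) are
config keys with these defaults. Every run writes per-stage TSV
checkpoints plus a `manifest.json` with the config hash and per-stage
seeds/row counts; identical configs reproduce byte-identical outputs.

## Module map

| module | contents |
| --- | --- |
| `hfcommons.io_formats` | validated containers + readers/writers (matrix TSV, sample sheet, GMT, edge list) |
| `hfcommons.stats_core` | ranking, one-sided Fisher, BH step-up, Mann-Whitney AUC, one-sample t |
| `hfcommons.synthetic_data` | planted-signal compendium generator + truth manifest |
| `hfcommons.rankprod_de` | tier 1: rank products, permutation p/pfp, DEG calls |
| `hfcommons.gsea_prerank` | tier 2: collection filtering, per-sample metric, ES, permutation p |
| `hfcommons.consensus` | gene/pathway frequency consensus, sharing profile, scatter coordinates, flat ORA |
| `hfcommons.tf_pathway` | tier 3: TF→pathway over-representation screen |
| `hfcommons.classifier_eval` | pooled-CV random-forest AUC + random-gene baseline |
| `hfcommons.pipeline` / `hfcommons.cli` | orchestration, YAML config, CLI |
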