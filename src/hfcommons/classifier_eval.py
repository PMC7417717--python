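"""Discriminative-power evaluation of a gene signature.

Builds a pooled samples x genes feature matrix across all datasets
(dropping genes not detected everywhere), runs stratified 10-fold
cross-validation with a random-forest classifier, pools the out-of-fold
scores into a single ROC AUC, and compares against a baseline of repeated
random same-size gene draws with a one-sample t-test.

Samples are pooled across datasets without batch correction, so the AUC is
optimistic under dataset confounding; leave-study-out validation is out of
scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io_formats import ExpressionCompendium
from .stats_core import one_sample_t, roc_auc

logger = logging.getLogger(__name__)

__all__ = ["ClassifierReport", "build_feature_matrix", "cv_auc", "random_gene_baseline", "evaluate_signature"]

N_FOLDS = 10
N_TREES = 500


@dataclass
class ClassifierReport:
    features_used: list
    auc: float
    fold_assignments: pd.Series
    null_aucs: list = field(default_factory=list)
    null_mean: float = float("nan")
    t_p: float = float("nan")
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_features": len(self.features_used),
            "features_used": list(self.features_used),
            "auc": self.auc,
            "null_mean_auc": self.null_mean,
            "n_null_repeats": len(self.null_aucs),
            "t_p": self.t_p,
            "seed": self.seed,
        }


def detected_everywhere(comp: ExpressionCompendium) -> pd.Index:
    """Genes present in every dataset of the compendium."""
    genes = comp.datasets[0].genes
    for ds in comp.datasets[1:]:
        genes = genes.intersection(ds.genes)
    return genes


def build_feature_matrix(comp: ExpressionCompendium, genes) -> tuple:
    """Pooled (samples x genes) matrix and disease labels.

    Genes absent from any dataset are dropped (logged); rows cover every
    sample of every dataset.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    everywhere = set(detected_everywhere(comp))
    kept = [g for g in genes if g in everywhere]
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("dropped %d/%d feature genes not detected in all datasets", dropped, len(genes))
    if not kept:
        raise ValueError("no feature gene is detected in all datasets")
    blocks = []
    labels = []
    for ds in comp.datasets:
        blocks.append(ds.matrix.loc[kept].T)
        labels.append((ds.samples["group"] == "disease").astype(int))
    features = pd.concat(blocks, axis=0)
    y = pd.concat(labels, axis=0)
    return features, y


def cv_auc(features: pd.DataFrame, labels: pd.Series, n_folds: int = N_FOLDS, n_trees: int = N_TREES, seed: int = 0) -> tuple:
    """Stratified k-fold RF cross-validation with pooled out-of-fold AUC.

    Returns ``(auc, predictions)`` where predictions carries the held-out
    score and fold id per sample.
    """
    y = np.asarray(labels, dtype=int)
    x = features.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < n_folds:
        raise ValueError("fewer samples than folds")
    if min(np.bincount(y)) < n_folds:
        raise ValueError("stratified folds infeasible: a class has fewer samples than folds")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(splitter.split(x, y)):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + fold)
        clf.fit(x[train], y[train])
        scores[test] = clf.predict_proba(x[test])[:, 1]
        folds[test] = fold
    auc = roc_auc(scores, y.astype(bool))
    predictions = pd.DataFrame({"score": scores, "label": y, "fold": folds}, index=features.index)
    return auc, predictions


def random_gene_baseline(
    comp: ExpressionCompendium,
    k: int,
    observed_auc: float,
    n_repeats: int = 1000,
    n_folds: int = N_FOLDS,
    n_trees: int = N_TREES,
    seed: int = 0,
) -> tuple:
    """AUC null distribution from random size-``k`` gene draws.

    Returns ``(null_aucs, mean, t_p)``; the t-test (null mean below the
    observed AUC) needs at least 3 repeats and is NaN otherwise.
    """
    pool = list(detected_everywhere(comp))
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)}-gene candidate pool")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_repeats)
    null_aucs = []
    for child in children:
        rng = np.random.default_rng(child)
        draw = [pool[i] for i in rng.choice(len(pool), k, replace=False)]
        features, labels = build_feature_matrix(comp, draw)
        auc, _ = cv_auc(features, labels, n_folds=n_folds, n_trees=n_trees, seed=int(rng.integers(2**31)))
        null_aucs.append(auc)
    mean = float(np.mean(null_aucs))
    if n_repeats >= 3 and np.std(null_aucs, ddof=1) > 0:
        t_p = one_sample_t(null_aucs, observed_auc)
    else:
        t_p = float("nan")  # refused: too few repeats or degenerate null
    return null_aucs, mean, t_p


def evaluate_signature(
    comp: ExpressionCompendium,
    genes,
    n_folds: int = N_FOLDS,
    n_trees: int = N_TREES,
    n_repeats: int = 50,
    seed: int = 0,
) -> ClassifierReport:
    """Observed signature AUC plus random-gene baseline in one report."""
    features, labels = build_feature_matrix(comp, genes)
    auc, predictions = cv_auc(features, labels, n_folds=n_folds, n_trees=n_trees, seed=seed)
    null_aucs, null_mean, t_p = random_gene_baseline(
        comp, k=features.shape[1], observed_auc=auc,
        n_repeats=n_repeats, n_folds=n_folds, n_trees=n_trees, seed=seed + 1,
    )
    return ClassifierReport(
        features_used=list(features.columns),
        auc=auc,
        fold_assignments=predictions["fold"],
        null_aucs=null_aucs,
        null_mean=null_mean,
        t_p=t_p,
        seed=seed,
    )
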