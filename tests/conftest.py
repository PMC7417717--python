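import numpy as np
import pandas as pd
import pytest

from hfcommons.consensus import GeneConsensus  # noqa: F401  (re-export convenience)
from hfcommons.gsea_prerank import SampleEnrichment
from hfcommons.rankprod_de import DEResult
from hfcommons.synthetic_data import GeneratorConfig, generate_compendium


SMALL_CFG = GeneratorConfig(
    n_genes=400,
    n_comparisons=8,
    n_conditions=4,
    n_fdeg=30,
    n_pathways=30,
    n_core_pathways=4,
    n_active_pathways_per_condition=6,
    n_redundant_pathways=3,
    n_tfs=12,
    n_linked_tfs=6,
    tf_pathway_coverage=0.5,
    tf_random_targets=10,
    pathway_size_range=(8, 16),
    n_disease_range=(5, 8),
    n_control_range=(4, 6),
    seed=101,
)


@pytest.fixture(scope="session")
def small_bundle():
    """(compendium, collection, network, manifest) at test scale."""
    return generate_compendium(SMALL_CFG)


@pytest.fixture(scope="session")
def small_compendium(small_bundle):
    return small_bundle[0]


@pytest.fixture()
def make_de_result():
    """Factory for fabricated tier-1 results with given per-gene calls."""

    def _make(comparison_id, calls, ratios=None):
        genes = list(calls)
        table = pd.DataFrame(index=pd.Index(genes, name="gene"))
        table["rp_up"] = 1.0
        table["rp_down"] = 1.0
        table["p_up"] = 0.5
        table["p_down"] = 0.5
        table["pfp_up"] = 0.5
        table["pfp_down"] = 0.5
        table["avg_log_ratio"] = [0.0 if ratios is None else ratios[g] for g in genes]
        table["call"] = [calls[g] for g in genes]
        return DEResult(comparison_id=comparison_id, table=table)

    return _make


@pytest.fixture()
def make_enrichment():
    """Factory for fabricated per-sample enrichment results.

    ``rows`` maps pathway -> (es, p); significance uses p < 0.05.
    """

    def _make(sample_id, rows, condition="C0", comparison_id="CMP0"):
        table = pd.DataFrame(
            [
                (name, es, p, bool(p < 0.05 and es != 0.0), "up" if es > 0 else ("down" if es < 0 else "none"))
                for name, (es, p) in rows.items()
            ],
            columns=["pathway", "es", "p", "significant", "direction"],
        ).set_index("pathway")
        return SampleEnrichment(sample_id=sample_id, comparison_id=comparison_id, condition=condition, table=table)

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
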