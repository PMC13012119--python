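import pytest

from regdiscover.core_io import ExpressionAtlas, parse_stage
from regdiscover.synthetic_data import AtlasSimConfig, simulate_atlas


def build_atlas(values: dict[tuple[str, str, str], float]) -> ExpressionAtlas:
    """Construct an atlas directly from a {(gene, organ, stage): rpkm} dict."""
    genes = sorted({k[0] for k in values})
    organs = list(dict.fromkeys(k[1] for k in values))
    stages = {
        o: sorted({parse_stage(k[2]) for k in values if k[1] == o})
        for o in organs
    }
    return ExpressionAtlas(genes=genes, organs=organs, stages=stages, values=values)


@pytest.fixture(scope="session")
def default_sim():
    """The default planted synthetic atlas (2,000 genes, 7 organs, 14 stages,
    50 enriched per organ at fold 8, cv 0.2, seed 1)."""
    return simulate_atlas(AtlasSimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A small planted atlas for oracle comparisons."""
    cfg = AtlasSimConfig(seed=7, n_genes=200, n_enriched_per_organ=10,
                         missing_rate=0.05)
    return simulate_atlas(cfg)
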