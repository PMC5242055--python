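import numpy as np
import pytest

from epimodules.genome_context import ContextDefinition, GeneModel, Locus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_genes():
    return [
        GeneModel("GENEA", "chr1", 1000, 5000, "+"),
        GeneModel("GENEB", "chr1", 20000, 26000, "+"),
        GeneModel("GENEC", "chr1", 40000, 45000, "-"),
    ]


@pytest.fixture
def promoter_ctx():
    return ContextDefinition(
        name="promoter",
        track_id="meth",
        interval_rule=("promoter_window", 1000, 500),
        context_weight=1.0,
        direction_coefficient=-1,
    )


@pytest.fixture
def body_ctx():
    return ContextDefinition(
        name="body",
        track_id="meth",
        interval_rule=("gene_body",),
        context_weight=1.0,
        direction_coefficient=0,
    )


def make_loci(positions, p_values, effects=None, chrom="chr1", track="meth"):
    if effects is None:
        effects = [1.0] * len(positions)
    return [
        Locus(track, chrom, pos, eff, p)
        for pos, eff, p in zip(positions, effects, p_values)
    ]


@pytest.fixture
def small_fixture_dir(tmp_path_factory):
    """A complete small synthetic input set shared by pipeline-level tests."""
    from epimodules.simulate import SimulationConfig, simulate_genome, simulate_network

    out = tmp_path_factory.mktemp("fixture")
    cfg = SimulationConfig(
        n_genes=200,
        n_planted=15,
        effect_shift=3.0,
        seed=42,
        network_model=("planted_partition", [15, 185], 0.5, 0.005, 0.02),
    )
    paths = simulate_genome(cfg, out)
    planted = set(paths["planted"].read_text().split())
    edge_path, truth_path = simulate_network(cfg, out, planted=planted)
    paths["network"] = edge_path
    paths["community"] = truth_path
    return paths
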