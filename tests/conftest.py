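import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from tulip import (
    SimConfig,
    SimplifyConfig,
    build_graph,
    extract_paths,
    join_long_range,
    misjoin_report,
    run_simulation,
    simplify_graph,
    truth_chains,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@dataclasses.dataclass
class PipelineResult:
    sim: object
    chains: list
    graph: object
    initial_link_keys: set
    n_initial_links: int
    models: list
    report: object


def run_pipeline(sim, cfg=None) -> PipelineResult:
    cfg = cfg or SimplifyConfig()
    seed_len = sim.config.seed_len
    chains = truth_chains(sim.truth, seed_len)
    graph = build_graph(chains, seed_len)
    initial_keys = {key for key, _ in graph.iter_links()}
    n_initial = len(initial_keys)
    simplify_graph(graph, cfg)
    models = extract_paths(graph, cfg)
    models = join_long_range(models, chains, cfg, seed_len)
    report = misjoin_report(models, sim.truth, seed_len)
    return PipelineResult(
        sim=sim,
        chains=chains,
        graph=graph,
        initial_link_keys=initial_keys,
        n_initial_links=n_initial,
        models=models,
        report=report,
    )


@pytest.fixture(scope="session")
def golden_sim():
    """1 Mbp genome, seeds at ~1/700 bp, 15x error-free ~8 kbp reads."""
    return run_simulation(SimConfig(genome_len=1_000_000, chemistry="perfect", rng_seed=42))


@pytest.fixture(scope="session")
def golden_result(golden_sim):
    return run_pipeline(golden_sim)


@pytest.fixture(scope="session")
def noisy_sim():
    """Same conditions at R9-1D-like identity (0.89) with 15% of truth seed
    alignments randomly dropped."""
    return run_simulation(
        SimConfig(genome_len=1_000_000, chemistry="r9-1d", missed_hit_rate=0.15, rng_seed=42)
    )


@pytest.fixture(scope="session")
def noisy_result(noisy_sim):
    return run_pipeline(noisy_sim)


@pytest.fixture(scope="session")
def small_sim():
    """100 kbp perfect-read simulation for cheap unit-level checks."""
    return run_simulation(SimConfig(genome_len=100_000, chemistry="perfect", rng_seed=7))
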