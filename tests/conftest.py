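import pytest

from nampower import GeneticMap, synth_founders
from nampower.pipeline import build_population
from nampower.config import ScenarioConfig


@pytest.fixture(scope="session")
def two_chrom_map() -> GeneticMap:
    """20 markers on two 50 cM chromosomes."""
    return GeneticMap.uniform({"1": 50.0, "2": 50.0}, 20)


@pytest.fixture(scope="session")
def small_panel():
    """Small synthetic founder panel: 2 x 6 founders + common, 120 markers."""
    return synth_founders(6, 6, 120, divergence=0.4, rng=123,
                          chrom_lengths_cm={"1": 60.0, "2": 60.0})


@pytest.fixture(scope="session")
def tiny_scenario():
    """Desk-scale scenario: 4 subpops x 30, 200 markers, 10 QTLs."""
    return ScenarioConfig(
        n_subpops=4,
        n_per_sub=30,
        n_markers=200,
        n_qtl=10,
        geometric_a=0.8,
        chrom_lengths_cm={"1": 80.0, "2": 80.0},
        n_runs=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bc_pop(tiny_scenario):
    from nampower.pipeline import build_founders
    from nampower._rng import child_rng

    panel = build_founders(tiny_scenario)
    return panel, build_population(panel, tiny_scenario, child_rng(7, "design", 0))
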