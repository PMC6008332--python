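import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spliceratio.simulate import (
    SimulationConfig,
    simulate_gene_models,
    simulate_junction_counts,
)


@pytest.fixture(scope="session")
def small_mixed_models():
    """A few genes of every event type, both strands, with counts."""
    config = SimulationConfig(
        events_per_type={"CA": 4, "A3SS": 4, "A5SS": 4, "MXE": 4},
        n_planted=0,
        seed=5,
    )
    annotation, planted = simulate_gene_models(config)
    sim = simulate_junction_counts(planted, config, np.random.default_rng(config.seed))
    return config, annotation, planted, sim


@pytest.fixture(scope="session")
def planted_detection_run():
    """One full detection run at the default study conditions."""
    from spliceratio.detect import detect

    config = SimulationConfig(seed=17)
    annotation, planted = simulate_gene_models(config)
    sim = simulate_junction_counts(planted, config, np.random.default_rng(config.seed))
    result = detect(sim.counts, sim.treatment_ids, sim.control_ids, annotation)
    return config, sim, result
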