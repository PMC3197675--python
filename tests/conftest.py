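import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "crgpipe",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("crgpipe")


@pytest.fixture(scope="session")
def pool_recovery():
    """The standard parameter-recovery simulation: 1000 strains, 50 with a
    one-doubling fitness defect, 0.25 log2 noise, 3+3 replicates."""
    from crgpipe import barcode_fitness as bf
    from crgpipe import synthio

    spec = synthio.pool_spec_with_effects(
        1000, 50, -1.0, noise_sd_log2=0.25, seed=20250929
    )
    matrix, truth = synthio.simulate_pool_experiment(spec)
    table = bf.pool_fitness(matrix)
    merged = table.records.merge(truth, on="strain_id")
    return spec, table, merged
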