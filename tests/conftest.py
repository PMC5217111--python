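import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hypoxtc.counts_io import CountMatrix, SampleInfo
from hypoxtc.preprocess import floor_values, total_count_normalize
from hypoxtc.simulate import default_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

HYPOXIA_TIMES = (0.0, 5.0, 10.0, 30.0, 60.0, 120.0, 180.0, 240.0)


def make_matrix(values, times=None, gene_ids=None) -> CountMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    times = list(times) if times is not None else list(HYPOXIA_TIMES[: values.shape[1]])
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = [SampleInfo(f"t{int(t)}", t) for t in times]
    return CountMatrix(list(gene_ids), samples, values)


@pytest.fixture(scope="session")
def scenario():
    """One full-size default scenario shared across the session."""
    return default_scenario(seed=1, n_genes=6000)


@pytest.fixture(scope="session")
def scenario_processed(scenario):
    matrix, truths = scenario
    normalized = total_count_normalize(matrix)
    return matrix, truths, normalized, floor_values(normalized)
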