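import pytest
from hypothesis import HealthCheck, settings

from interneuron_profiler import oxphos, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """Default 9 control / 5 SUDEP / 14 patient cohort."""
    return synthetic.generate_cohort(synthetic.CohortSpec(seed=101))


@pytest.fixture(scope="session")
def model():
    return synthetic.IntensityModel(seed=202)


@pytest.fixture(scope="session")
def classified_cells(model, cohort):
    """Full cohort cell table, classified against pooled controls."""
    cells = synthetic.generate_cell_intensity_table(model, cohort)
    ratios = oxphos.compute_ratios(cells)
    return oxphos.classify_cells(ratios)
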