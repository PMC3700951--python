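import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mefvrisk import GenotypeTally, PopulationParams  # noqa: E402


@pytest.fixture
def study_populations():
    """The four published population parameter sets."""
    return [
        PopulationParams("Armenian", q_strict=0.07),
        PopulationParams(
            "Sephardic", q_strict=0.09, q_inclusive=0.14,
            prevalence_observed_low=0.001, prevalence_observed_high=0.004,
        ),
        PopulationParams("Arab", q_strict=0.04),
        PopulationParams(
            "Turkish", q_strict=0.05, q_inclusive=0.1,
            prevalence_observed_low=0.001, prevalence_observed_high=0.001,
        ),
    ]


@pytest.fixture
def unexplained_tallies():
    """Published genotype tallies of genetically-unexplained patients."""
    return [
        GenotypeTally(0, 25, 19, "Armenian"),
        GenotypeTally(0, 41, 25, "Sephardic"),
        GenotypeTally(0, 38, 98, "Arab"),
        GenotypeTally(0, 15, 24, "Turkish"),
    ]
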