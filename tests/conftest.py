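import pytest
from hypothesis import HealthCheck, settings

from drgsd import (
    DR_GSD,
    GSD,
    RR_GSD,
    DesignSpec,
    solve_boundaries,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The packaged worked example: schizophrenia trial, Pocock-like spending,
# interim at 29% information with 30% in the pipeline.
EXAMPLE_DELTA = 1.6


def example_spec(kind: str = GSD) -> DesignSpec:
    return DesignSpec(
        alpha=0.025,
        beta=0.2,
        sigma=7.5,
        n_max=345.0,
        info_interim=0.29,
        info_pipeline=0.3,
        spending_family="pocock_like",
        design_kind=kind,
    )


@pytest.fixture(scope="session")
def gsd_example():
    spec = example_spec(GSD)
    return spec, solve_boundaries(spec)


@pytest.fixture(scope="session")
def dr_example():
    spec = example_spec(DR_GSD)
    return spec, solve_boundaries(spec)


@pytest.fixture(scope="session")
def rr_example():
    spec = example_spec(RR_GSD)
    return spec, solve_boundaries(spec)
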