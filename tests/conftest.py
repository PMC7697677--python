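import pytest
from hypothesis import HealthCheck, settings

from at1screen.io_formats import RunConfig
from at1screen.pipeline import run_pipeline
from at1screen.synthetic_data import (
    SimSpec,
    simulate_counts,
    simulate_external_sets,
    simulate_organ_matrix,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_spec():
    return SimSpec()


@pytest.fixture(scope="session")
def sim_bundle(default_spec):
    """Everything the pipeline needs, simulated once at the default spec."""
    cm, truth = simulate_counts(default_spec)
    organ = simulate_organ_matrix(default_spec)
    external, orthologs, localization, foreign = simulate_external_sets(
        truth, default_spec
    )
    return {
        "spec": default_spec,
        "counts": cm,
        "truth": truth,
        "organ": organ,
        "external": external,
        "orthologs": orthologs,
        "localization": localization,
        "foreign": foreign,
    }


@pytest.fixture(scope="session")
def pipeline_result(sim_bundle):
    """One full default-configuration run, shared by the read-only tests."""
    return run_pipeline(
        sim_bundle["counts"],
        sim_bundle["external"],
        sim_bundle["foreign"],
        sim_bundle["orthologs"],
        sim_bundle["organ"],
        sim_bundle["localization"],
        RunConfig(),
        correlation_pairs=(("Aqp5", "tdTomato"),),
    )
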