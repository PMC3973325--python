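import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gantcscope.synthetic import (  # noqa: E402
    SyntheticPlan,
    generate_genome,
    generate_ipd_dataset,
    generate_methylation_plan,
)


@pytest.fixture(scope="session")
def small_plan():
    """A 60-kb study small enough for per-test generation."""
    return SyntheticPlan(
        seed=11,
        genome_length=60_000,
        n_genes=60,
        gene_length_mean=500,
        n_under=4,
        n_asym=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_plan):
    genome, features, sites = generate_genome(small_plan)
    return small_plan, genome, features, sites


@pytest.fixture(scope="session")
def small_methylome(small_bundle):
    plan, genome, features, sites = small_bundle
    meth = generate_methylation_plan(plan, sites["site"].to_numpy())
    obs = generate_ipd_dataset(genome, meth, plan)
    ref = generate_ipd_dataset(genome, meth, plan, reference=True)
    return plan, genome, sites, meth, obs, ref


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
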