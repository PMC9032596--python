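import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def small_config():
    """Two-chromosome cross with one strong locus: fast but non-trivial."""
    from mesoqtl import simdata

    return simdata.SimConfig(
        seed=7,
        n_f2=200,
        n_chromosomes=2,
        markers_per_chromosome=(10, 10),
        chromosome_lengths=(100.0, 80.0),
        environments=("20cm",),
        env_means=(13.0,),
        residual_sd=(2.0,),
        gxe_sd=0.0,
        qtl_architecture=(
            simdata.TrueQTL("q1", 1, 45.0, {"20cm": -1.25}, {"20cm": -0.18}),
        ),
        variant_sites_per_chromosome=100,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config, tmp_path_factory):
    from mesoqtl import simdata

    outdir = tmp_path_factory.mktemp("scenario")
    return simdata.scenario_study(small_config, outdir)
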