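import logging

import pytest

from ssrlink import GeneratorConfig, PipelineConfig, run_pipeline

logging.getLogger("ssrlink").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_bundle():
    """One full pipeline run on the default synthetic study conditions."""
    config = PipelineConfig(generator=GeneratorConfig(), seed=1)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def small_pools():
    """A small synthetic data set with truth, shared across unit tests."""
    from ssrlink.synthetic_data import generate_pools

    config = GeneratorConfig(
        seed=11,
        n_shared_loci=30,
        n_female_specific_loci=6,
        n_male_specific_loci=6,
        n_background_scaffolds=8,
    )
    male, female, truth = generate_pools(config)
    return config, male, female, truth
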