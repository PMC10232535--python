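import pytest

from chirtransfer import (
    RegressorSpec,
    SyntheticSPRConfig,
    encode_dataset,
    fit_base,
)
from chirtransfer.synthetic import (
    generate_descriptor_library,
    generate_source_domain,
    generate_target_domain,
    make_latent,
    make_perturbation,
)


@pytest.fixture(scope="session")
def campaign():
    """One default synthetic campaign (seed 0), shared read-only across tests."""
    cfg = SyntheticSPRConfig(seed=0)
    lib = generate_descriptor_library(cfg)
    latent = make_latent(cfg, lib)
    perturbation = make_perturbation(cfg, lib)
    source = generate_source_domain(cfg, lib, latent)
    target = generate_target_domain(cfg, lib, latent, perturbation)
    return {
        "config": cfg,
        "lib": lib,
        "latent": latent,
        "perturbation": perturbation,
        "source": source,
        "target": target,
    }


@pytest.fixture(scope="session")
def source_dataset(campaign):
    return encode_dataset(campaign["source"], campaign["lib"].tables)


@pytest.fixture(scope="session")
def base_model(source_dataset):
    return fit_base(source_dataset, RegressorSpec("linear_svr"), seed=0)
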