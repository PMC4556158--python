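import numpy as np
import pytest

from tetrabin.synthetic import CommunitySpec, build_community, generate_genome
from tetrabin.tdp import build_model, default_model


@pytest.fixture(scope="session")
def two_genomes():
    """Two 1 Mb genomes with distinct compositional signatures."""
    return [
        ("gA", generate_genome(2, 5.0, 1_000_000, 11)),
        ("gB", generate_genome(2, 5.0, 1_000_000, 22)),
    ]


@pytest.fixture(scope="session")
def small_model(two_genomes):
    """Distance model trained on the two-genome corpus at 2.5 kb and 20 kb."""
    return build_model(two_genomes, size_grid=(2500, 20000), pairs_per_cell=4000, rng_seed=3)


@pytest.fixture(scope="session")
def bundled_model():
    return default_model()


@pytest.fixture(scope="session")
def default_community():
    """The default benchmark community: 10 genomes x 5 samples, seed 42."""
    spec = CommunitySpec()
    contigs, profiles, truth = build_community(spec)
    return spec, contigs, profiles, truth


@pytest.fixture(scope="session")
def default_run(default_community, bundled_model, tmp_path_factory):
    from tetrabin.pipeline import run_binning

    _, contigs, profiles, _ = default_community
    outdir = tmp_path_factory.mktemp("default_run")
    return run_binning(contigs, profiles, outdir, model=bundled_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
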