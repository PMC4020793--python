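import numpy as np
import pytest

from tgmap.locus import build_alleles, default_locus_spec
from tgmap.model import IntegrationSiteModel, PipelineConfig
from tgmap.simulate import ReadSimParams, emit_oracle_alignments, simulate_read_pairs

DEFAULT_SEED = 8


@pytest.fixture(scope="session")
def default_spec():
    return default_locus_spec(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def genome(default_spec):
    return build_alleles(default_spec)


@pytest.fixture(scope="session")
def sim_pairs_clean(genome):
    """Error-free read pairs from the default hom genome."""
    params = ReadSimParams(seed=DEFAULT_SEED, error_rate=0.0)
    return simulate_read_pairs(genome, params), params


@pytest.fixture(scope="session")
def oracle_clean(genome, sim_pairs_clean):
    pairs, _ = sim_pairs_clean
    return emit_oracle_alignments(genome, pairs)


@pytest.fixture(scope="session")
def fitted(genome):
    """Default study-condition run (hom, 8X, 1% error, seed 8), fitted."""
    model = IntegrationSiteModel.from_simulation(
        genome, ReadSimParams(seed=DEFAULT_SEED), PipelineConfig(seed=DEFAULT_SEED)
    )
    return model.fit()


@pytest.fixture(scope="session")
def multiseed_clean_runs(genome):
    """Twenty error-free runs of the default locus across seeds."""
    out = []
    for seed in range(1, 21):
        model = IntegrationSiteModel.from_simulation(
            genome,
            ReadSimParams(seed=seed, error_rate=0.0),
            PipelineConfig(seed=seed),
        )
        out.append((seed, model.fit()))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
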