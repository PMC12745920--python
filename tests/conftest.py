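import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from refugia.engine import EngineConfig
from refugia.genotypes import GenotypeMatrix

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

#: cheaper engine for fitting experiments (documented accuracy ~0.7%)
FIT_ENGINE = EngineConfig(grid_sizes=(25, 35, 45), time_step_factor=0.015)


@pytest.fixture(scope="session")
def fit_engine():
    return FIT_ENGINE


def make_gm(genotypes, pops=("A", "B"), dp=30, gq=99, loci=None,
            snp_index=None):
    """Small genotype matrix from a nested list; columns are split evenly
    between two populations unless an explicit sample->pop map is given."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    dp = np.full_like(g, dp, dtype=np.int32) if np.isscalar(dp) \
        else np.asarray(dp, dtype=np.int32)
    gq = np.full_like(g, gq, dtype=np.int32) if np.isscalar(gq) \
        else np.asarray(gq, dtype=np.int32)
    if loci is None:
        loci = [f"L{k}" for k in range(n_sites)]
    if snp_index is None:
        snp_index = [0] * n_sites
    samples = [f"s{j}" for j in range(n_samples)]
    if isinstance(pops, dict):
        pop_map = pops
    else:
        half = n_samples // 2
        pop_map = {s: (pops[0] if j < half else pops[1])
                   for j, s in enumerate(samples)}
    return GenotypeMatrix(g, dp, gq, np.array(loci, dtype=object),
                          np.array(snp_index), samples, pop_map)
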