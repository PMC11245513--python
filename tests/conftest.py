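import numpy as np
import pytest

from pleioscan import LDModel, RegionSummary, SimScenario, simulate_ld, \
    simulate_region


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_region(z, query_index=0, maf=None, n=20_000.0, s=0.5,
                trait_id="t", se=None, chrom="1"):
    """Small RegionSummary from a z vector (se defaults to 1)."""
    z = np.asarray(z, dtype=float)
    q = z.size
    se = np.ones(q) if se is None else np.asarray(se, dtype=float)
    maf = np.full(q, 0.3) if maf is None else np.asarray(maf, dtype=float)
    return RegionSummary(
        snp_ids=[f"{chrom}_{1000 + i}_A_G" for i in range(q)],
        positions=np.arange(1000, 1000 + q),
        maf=maf,
        n=n,
        query_index=query_index,
        trait_id=trait_id,
        trait_type="cc",
        beta=z * se,
        se=se,
        s=s,
    )


@pytest.fixture
def small_region():
    return make_region([0.5, -1.2, 3.5, 0.0, 2.0], query_index=2)


@pytest.fixture
def ar1_ld():
    ld, maf = simulate_ld(20, LDModel(kind="ar1", rho=0.8), seed=7)
    return ld, maf


def simulate_one(truth, Q, query_index, causal, log_ors, ld, maf, seed,
                 trait_id="sim"):
    scenario = SimScenario(truth=truth, Q=Q, query_index=query_index,
                           causal_indices=causal, causal_log_ors=log_ors,
                           trait_id=trait_id)
    return simulate_region(scenario, ld, maf, rng=seed)
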