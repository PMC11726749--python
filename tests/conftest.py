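import numpy as np
import pytest

from mrpipe.gwas_io import SNPAssociation
from mrpipe.instruments import HarmonizedSet
from mrpipe.simulate import SimulationConfig, simulate_triplet


def make_assoc(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
               beta=0.1, se=0.01, pval=1e-6, eaf=0.3, n=10_000):
    return SNPAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                          effect_allele=ea, other_allele=oa,
                          beta=beta, se=se, pval=pval, eaf=eaf, n=n)


def random_harmonized(rng: np.random.Generator, k: int = 5,
                      slope: float = 0.3) -> HarmonizedSet:
    """A small harmonized set whose outcome betas follow a noisy line."""
    beta_exp = rng.uniform(0.05, 0.3, size=k) * rng.choice([-1, 1], size=k)
    se_exp = rng.uniform(0.005, 0.02, size=k)
    se_out = rng.uniform(0.005, 0.03, size=k)
    beta_out = slope * beta_exp + rng.normal(0.0, se_out)
    return HarmonizedSet(
        snp_ids=[f"rs{i}" for i in range(k)],
        beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out,
        flipped=np.zeros(k, dtype=bool),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def harmonized5(rng):
    return random_harmonized(rng, k=5)


@pytest.fixture(scope="session")
def mediated_triplet():
    """One simulated triplet with a genuine mediated effect."""
    cfg = SimulationConfig(
        n_snps=150, beta_exp_med=0.2, beta_med_out=0.3,
        beta_exp_out_direct=0.1, pleiotropy_sd=0.1, seed=7,
    )
    return simulate_triplet(cfg)
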