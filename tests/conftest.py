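import numpy as np
import pytest

from gutmr import (HarmonizedInstrument, SNPAssociation, SimulationConfig,
                   SummaryStats, harmonize, retained, simulate_sumstats)


def make_snp(variant_id="rs1", chromosome="1", position=1000, ea="A", oa="G",
             eaf=0.3, beta=0.1, se=0.02, pvalue=None, n=None):
    if pvalue is None:
        from scipy import stats as sps
        pvalue = float(min(max(2 * sps.norm.sf(abs(beta / se)), 1e-300), 1.0))
    return SNPAssociation(variant_id, chromosome, position, ea, oa, eaf,
                          beta, se, pvalue, n)


@pytest.fixture
def snp_factory():
    return make_snp


def make_harmonized(bx, sx, by, sy, ids=None):
    ids = ids or [f"rs{i}" for i in range(len(bx))]
    return [HarmonizedInstrument(variant_id=i, beta_exp=float(x), se_exp=float(s),
                                 beta_out=float(y), se_out=float(t))
            for i, x, s, y, t in zip(ids, bx, sx, by, sy)]


@pytest.fixture
def harmonized_factory():
    return make_harmonized


def simulate_harmonized(n_snps=10, theta=0.14, seed=0, n_exp=200_000.0,
                        n_out=60_620.0, pleiotropy_mode="none",
                        pleiotropy_sd=0.0, pleiotropy_mean=0.0, rng=None):
    """Strong-instrument harmonized set straight from the generator."""
    cfg = SimulationConfig(n_snps=n_snps, theta=theta, seed=seed, n_exp=n_exp,
                           n_out=n_out, pleiotropy_mode=pleiotropy_mode,
                           pleiotropy_sd=pleiotropy_sd,
                           pleiotropy_mean=pleiotropy_mean)
    exp, out, truth = simulate_sumstats(cfg, rng=rng)
    return retained(harmonize(exp.records, out)), truth


@pytest.fixture
def harmonized_sim():
    return simulate_harmonized
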