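import numpy as np
import pytest

from adipomr.sumstats import HarmonizedSet, SNPAssociation, SummaryDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)


def make_record(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.02, se=0.005,
                pvalue=1e-4, n=10000):
    return SNPAssociation(snp_id, ea, oa, eaf, beta, se, pvalue, n)


def make_hset(gamma, Gamma, se_Gamma, se_gamma=None, gamma2=None, **kw):
    gamma = np.asarray(gamma, dtype=float)
    return HarmonizedSet(
        snp_ids=[f"rs{i+1}" for i in range(len(gamma))],
        gamma=gamma,
        se_gamma=np.full_like(gamma, 0.01) if se_gamma is None
        else np.asarray(se_gamma, dtype=float),
        Gamma=np.asarray(Gamma, dtype=float),
        se_Gamma=np.asarray(se_Gamma, dtype=float),
        gamma2=None if gamma2 is None else np.asarray(gamma2, dtype=float),
        se_gamma2=None if gamma2 is None else np.full_like(gamma, 0.01),
        **kw,
    )


@pytest.fixture
def hset_factory():
    return make_hset


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_dataset():
    return SummaryDataset(
        "waist",
        [
            make_record("rs1", "A", "G", 0.3, 0.03, 0.004, 1e-14),
            make_record("rs2", "C", "T", 0.5, -0.02, 0.004, 1e-9),
            make_record("rs3", "G", "C", 0.2, 0.04, 0.005, 1e-20),
        ],
    )
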