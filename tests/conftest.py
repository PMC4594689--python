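import pytest

from snpmeta import effect_for_outcome, group_by_snp, load_il2ra_t1d

SNPS = ("rs11594656", "rs2104286", "rs3118470", "rs41295061", "rs706778")


@pytest.fixture(scope="session")
def outcomes():
    return load_il2ra_t1d()


@pytest.fixture(scope="session")
def by_snp(outcomes):
    return group_by_snp(outcomes)


@pytest.fixture(scope="session")
def effects_by_snp(by_snp):
    """Reported-CI effect estimates per SNP, as used for pooling."""
    return {
        snp: [effect_for_outcome(o) for o in rows] for snp, rows in by_snp.items()
    }
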