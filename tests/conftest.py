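import numpy as np
import pytest

from semigwas import StoreMetadata, write_store
from semigwas.store import GenotypeBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_store(path, doses, chunk_snps=4, individual_ids=None, snp_ids=None):
    """Write an individuals x SNPs dose matrix into a container at `path`."""
    n, m = doses.shape
    meta = StoreMetadata(
        n_individuals=n,
        n_snps=m,
        snp_ids=snp_ids or [f"snp{j}" for j in range(m)],
        individual_ids=individual_ids or [f"ind{i}" for i in range(n)],
        chunk_snps=chunk_snps,
        chunk_individuals=n,
    )
    block = GenotypeBlock(doses=doses, snp_offset=0, snp_ids=meta.snp_ids)
    write_store(path, meta, [block])
    return meta


@pytest.fixture
def small_store(tmp_path, rng):
    """6 individuals x 10 SNPs of quantized random doses, plus the source matrix."""
    doses = np.round(rng.uniform(0, 2, size=(6, 10)), 2)
    path = tmp_path / "small.h5"
    meta = make_store(path, doses)
    return path, doses, meta
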