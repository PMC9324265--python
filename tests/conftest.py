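import numpy as np
import pytest

from mirpgs.datamodel import MISSING, GenotypeMatrix, SampleRecord, VariantRecord


def make_matrix(dosages, statuses=None, alleles=None):
    """Small helper for hand-built matrices in tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, k = dosages.shape
    variants = []
    for j in range(k):
        ea, oa = (alleles[j] if alleles else ("A", "G"))
        variants.append(
            VariantRecord(rsid=f"rs{j + 1}", chrom="1", pos=100 + j,
                          effect_allele=ea, other_allele=oa)
        )
    statuses = statuses or ["case" if i < n // 2 else "control" for i in range(n)]
    samples = [SampleRecord(sample_id=f"s{i + 1}", status=statuses[i]) for i in range(n)]
    return GenotypeMatrix(dosages, variants, samples)


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 variants with one missing call."""
    return make_matrix(
        [[0, 1, 2], [1, 1, 0], [2, MISSING, 1], [0, 2, 2]],
        statuses=["case", "case", "control", "control"],
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study (28 variants incl. proxies), fixed seed."""
    from mirpgs.simulate import default_config, simulate

    return simulate(default_config(seed=11))
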