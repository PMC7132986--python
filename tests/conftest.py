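import numpy as np
import pytest

from peelsim.pedigree import make_pedigree
from peelsim.simulate import DeskScale, generate_base_haplotypes


@pytest.fixture
def trio_ped():
    """Sire, dam, child."""
    return make_pedigree([1, 2, 3], [None, None, 1], [None, None, 2],
                         sex=["M", "F", "M"])


@pytest.fixture
def two_family_ped():
    """Six individuals: a shared grandsire, two mates, and full-sib pairs
    in two families (loop-free)."""
    #        1 (M)    2 (F)      5 (F)
    #          \       /   \      /
    #           3 (M, 4 F full sibs)   6 = child of 3 x 5
    return make_pedigree(
        [1, 2, 3, 4, 5, 6],
        [None, None, 1, 1, None, 3],
        [None, None, 2, 2, None, 5],
        sex=["M", "F", "M", "F", "F", "M"])


@pytest.fixture(scope="session")
def tiny_pool():
    """A very cheap founder pool for pedigree-machinery tests (small
    chromosome, short trajectory; not meant to be realistic)."""
    return generate_base_haplotypes(
        n_hap=60, n_chromosomes=2, seq_per_chr=60, hd_per_chr=20,
        ld_per_chr=10, chrom_length_bp=3e5, mu=2e-6, rec=3.3e-6,
        ne_trajectory=((0, 100), (100, 1000)), seed=11)


@pytest.fixture(scope="session")
def desk_pool():
    """The desk-scale founder pool shared by the end-to-end tests."""
    return DeskScale().founder_pool(seed=101)
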