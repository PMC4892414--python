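import numpy as np
import pytest

from pbwtsec import HaplotypePanel, keygen, make_rng


@pytest.fixture(scope="session")
def keypair():
    """One 512-bit Paillier key pair shared by the whole suite (test-size
    keys; production guidance is >= 2048 bits)."""
    return keygen(512, make_rng(12345))


@pytest.fixture()
def rng():
    return make_rng(987)


def random_panel(np_rng, m_max=12, n_max=24, alphabet=2) -> HaplotypePanel:
    m = int(np_rng.integers(2, m_max + 1))
    n = int(np_rng.integers(4, n_max + 1))
    return HaplotypePanel(np_rng.integers(0, alphabet, size=(m, n)),
                          alphabet_size=alphabet)


def brute_force_longest(panel: HaplotypePanel, query, t: int, eps: int = 1):
    """Oracle: scan all haplotypes for the longest common prefix with the
    query at position t, thresholded at eps."""
    query = np.asarray(query)
    ell = len(query)
    lcp = []
    for i in range(panel.M):
        row = panel.sequences[i, t - 1 : t - 1 + ell]
        j = 0
        while j < ell and row[j] == query[j]:
            j += 1
        lcp.append(j)
    length = max(
        (k for k in range(ell + 1) if sum(l >= k for l in lcp) >= eps), default=0
    )
    count = sum(l >= length for l in lcp)
    return length, count
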