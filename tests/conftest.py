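import numpy as np
import pytest


@pytest.fixture(scope="session")
def direct_dft():
    """Brute-force non-uniform DFT oracle for small grids."""

    def forward(img, k):
        N = img.shape[0]
        n = np.arange(N) - N // 2
        xx, yy, zz = np.meshgrid(n, n, n, indexing="ij")
        out = np.empty(len(k), complex)
        for j, kk in enumerate(np.asarray(k, float)):
            out[j] = np.sum(img * np.exp(-2j * np.pi *
                                         (kk[0] * xx + kk[1] * yy + kk[2] * zz) / N))
        return out

    return forward


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261002)
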