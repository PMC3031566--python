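import numpy as np
import pytest

from depthcnv.depth import BinTrack


def nbinom_counts(rng, mu, vmr, size):
    """Reference negative-binomial sampler (mean mu, variance vmr*mu)."""
    if vmr == 1:
        return rng.poisson(mu, size).astype(float)
    r = mu / (vmr - 1.0)
    return rng.negative_binomial(r, r / (r + mu), size).astype(float)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def flat_track(rng):
    """A 1000-bin diploid track with nbinom noise, full mapability."""
    counts = nbinom_counts(rng, 200.0, 3.0, 1000)
    return BinTrack(chrom="chr1", bin_size=1000, chrom_length=1_000_000,
                    counts=counts, mapability=np.ones(1000),
                    gc=rng.uniform(0.3, 0.6, 1000))
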