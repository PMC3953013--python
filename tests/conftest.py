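import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(chrom, pos, gt, samples, ref=None, alt=None, depth=None):
    """Small GenotypeMatrix builder for hand-written fixtures."""
    from neosexscan.io_formats import GenotypeMatrix

    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    assert n_samples == len(samples)
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object),
        gt=gt,
        depth=(np.asarray(depth, dtype=np.int32) if depth is not None
               else np.full((n_sites, n_samples), 50, dtype=np.int32)),
        samples=list(samples),
    )
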