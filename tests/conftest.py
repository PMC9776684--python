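import numpy as np
import pytest

from pathomsi.register import AffineTransform2D
from pathomsi.types import MsiDataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(n_spots=9, lo=700.0, hi=760.0, step=0.1, seed=0, peaks=((710.0, 1.0), (742.5, 0.8))):
    """Small hand-built MSI dataset: baseline + Gaussian peaks + noise."""
    rng = np.random.default_rng(seed)
    mz = np.arange(lo, hi + step / 2, step)
    side = int(np.ceil(np.sqrt(n_spots)))
    coords = np.array([(i % side, i // side) for i in range(n_spots)])
    base = 0.5 * np.exp(-(mz - lo) / 200.0)
    inten = np.empty((n_spots, mz.size))
    for i in range(n_spots):
        spec = base.copy()
        for m, a in peaks:
            spec += a * np.exp(-((mz - m) ** 2) / (2 * 0.1**2))
        spec += rng.normal(0, 0.02, mz.size)
        inten[i] = np.clip(spec, 0, None)
    return MsiDataset(mz_axis=mz, intensities=inten, coords=coords, section_id="fixture")


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def random_affine():
    def _make(seed):
        r = np.random.default_rng(seed)
        while True:
            lin = r.uniform(-3, 3, (2, 2))
            if abs(np.linalg.det(lin)) > 0.1:
                break
        t = r.uniform(-20, 20, 2)
        return AffineTransform2D(np.column_stack([lin, t]))
    return _make
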