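import numpy as np
import pytest

import pcbssfp as p


@pytest.fixture(scope="session")
def seq12():
    return p.SequenceParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def wm_point():
    """3 T white-matter reference relaxation values."""
    return p.TissueParams(t1=939.0, t2=62.0, b1=1.0)


@pytest.fixture(scope="session")
def uniform_grid_features(seq12):
    """Normalized magnitude features on a 50x50 tissue-range grid at
    theta=0, B1=1 (feasible points only)."""
    t1 = np.linspace(360, 2080, 50)
    t2 = np.linspace(20, 120, 50)
    tt1, tt2 = np.meshgrid(t1, t2, indexing="ij")
    keep = tt1.ravel() >= tt2.ravel()
    pts = p.TissueParams(
        t1=tt1.ravel()[keep], t2=tt2.ravel()[keep],
        b1=np.ones(keep.sum()), theta=np.zeros(keep.sum()),
    )
    sig = p.simulate_pc_signal(pts, seq12).values
    return pts, p.features_from_signal(sig, "magnitude", np.ones(keep.sum()))
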