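import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_titration():
    """Noiseless titration at the canonical design and truth parameters."""
    from aquakin.simulate import MstDesign, gen_mst_titration

    return gen_mst_titration(
        s1=1.0, s2=0.92, kd=29.0, design=MstDesign(), seed=1
    )
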