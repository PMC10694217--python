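import numpy as np
import pytest

from frlpsi import asr
from frlpsi.seqio import GroupedAlignment


@pytest.fixture(scope="session")
def lg():
    return asr.lg_model()


@pytest.fixture(scope="session")
def poisson():
    return asr.poisson_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_alignment():
    return GroupedAlignment(
        records=[
            ("frl_a", "SAGWRKLLYE"),
            ("frl_b", "SAGWRKLLYE"),
            ("vl_a", "GAGWRKILYE"),
        ],
        group_of={"frl_a": "FRL", "frl_b": "FRL", "vl_a": "VL"},
    )
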