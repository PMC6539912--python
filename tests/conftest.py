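import numpy as np
import pytest

from g4census import ScanParams

#: the perfectly repeated G-tract found in a cyanobacterial genome;
#: first 25-nt window of the 28-mer has mean base score 67/25 = 2.68
G_TRACT_28MER = "GGGGTGTGGGGTGTGGGGTGTGGGGTGT"


@pytest.fixture(scope="session")
def default_params():
    return ScanParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240517)


def random_sequence(rng, length, gc=0.5):
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )
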