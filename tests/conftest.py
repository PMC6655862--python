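import numpy as np
import pytest

import chancap as cc


@pytest.fixture(scope="session")
def identical_pair():
    """Two levels sharing one standard-normal output, n=2000 each."""
    return cc.simulate_channel(cc.identical_spec(2), 2000, seed=101)


@pytest.fixture(scope="session")
def disjoint_pair():
    """Two effectively disjoint Gaussian levels (means 0 and 100)."""
    return cc.simulate_channel(cc.gaussian_shift_spec([0.0, 100.0]), 1000, seed=102)


@pytest.fixture(scope="session")
def disjoint_four():
    """Four levels with mutually disjoint uniform supports, n=500 each."""
    return cc.simulate_channel(cc.disjoint_uniform_spec(4), 500, seed=103)


@pytest.fixture(scope="session")
def scenario1_sample():
    """The log-normal sigmoid benchmark channel in log-output coordinates."""
    return cc.simulate_channel(cc.scenario1_spec(), 1000, seed=104, log_output=True)


@pytest.fixture(scope="session")
def gaussian_triplet():
    """Three ordered Gaussian levels with moderate overlap, n=3000 each."""
    return cc.simulate_channel(cc.gaussian_shift_spec([0.0, 1.5, 3.0]), 3000, seed=105)


@pytest.fixture()
def tiny_table(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text("input,output1,output2\n0,1.0,2.0\n0,1.5,2.5\n1,3.0,4.0\n")
    return path


def make_sample(labels, outputs, columns=None):
    return cc.ChannelSample(labels, np.asarray(outputs, dtype=float), columns or [])
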