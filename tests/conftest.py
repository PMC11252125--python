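import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protoy.cli import run_demo
from protoy.seqs import random_orf

settings.register_profile(
    "protoy", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("protoy")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_gene():
    """A 303 bp complete ORF for fast structural tests."""
    return random_orf(np.random.default_rng(5), 101)


@pytest.fixture(scope="session")
def mv_demo(tmp_path_factory):
    out = tmp_path_factory.mktemp("mv_demo")
    t0 = time.time()
    report = run_demo("mv", 7, out)
    return {"report": report, "out": out, "elapsed": time.time() - t0}


@pytest.fixture(scope="session")
def miii_demo(tmp_path_factory):
    out = tmp_path_factory.mktemp("miii_demo")
    t0 = time.time()
    report = run_demo("miii", 7, out)
    return {"report": report, "out": out, "elapsed": time.time() - t0}
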