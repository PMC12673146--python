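import numpy as np
import pytest

from aquarisk import default_standards


@pytest.fixture(scope="session")
def standards():
    return default_standards()


@pytest.fixture(scope="session")
def by_code(standards):
    return {p.code: p for p in standards}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240707)


def random_sample(rng, by_code, which="wawqi"):
    """A random parameter→value map covering one index's parameter set."""
    values = {}
    for code, p in by_code.items():
        member = p.in_wawqi if which == "wawqi" else p.in_cpi
        if not member:
            continue
        if code == "PH":
            values[code] = rng.uniform(5.0, 9.0)
        elif code == "DO":
            values[code] = rng.uniform(2.0, 12.0)
        else:
            std = p.wawqi_standard or p.cpi_standard
            values[code] = rng.uniform(0.0, 3.0) * std
    return values
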