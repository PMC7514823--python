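import pytest

from poighl import PoiGHLParams, load_dataset


@pytest.fixture(scope="session")
def bladder():
    return load_dataset("bladder_cancer_128").values


@pytest.fixture(scope="session")
def mechanical():
    return load_dataset("mechanical_20").values


@pytest.fixture(scope="session")
def software():
    return load_dataset("software_34").values


@pytest.fixture(scope="session")
def fibers():
    return (
        load_dataset("fibers_20mm").values,
        load_dataset("fibers_50mm").values,
    )


@pytest.fixture(scope="session")
def param_grid():
    """Cross of shapes/rates spanning light and heavy tails."""
    return [
        PoiGHLParams(alpha, lam, a)
        for a in (0.3, 1.0, 3.0)
        for lam in (0.1, 1.0, 5.0)
        for alpha in (0.2, 1.0, 4.0)
    ]
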