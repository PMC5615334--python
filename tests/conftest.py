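import pytest

from secancer.cli_io import load_organ_params


@pytest.fixture(scope="session")
def breast():
    return load_organ_params("breast")


@pytest.fixture(scope="session")
def lung():
    return load_organ_params("lung")


@pytest.fixture(scope="session")
def thyroid():
    return load_organ_params("thyroid")


@pytest.fixture(scope="session")
def organs(breast, lung, thyroid):
    return {"breast": breast, "lung": lung, "thyroid": thyroid}
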