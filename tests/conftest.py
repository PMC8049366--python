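import dataclasses

import pytest

from mirdkit.nuclide import GA68
from mirdkit.synthetic import SubjectConfig, generate_subject


@pytest.fixture(scope="session")
def ga68():
    return GA68


@pytest.fixture(scope="session")
def noise_free_config():
    return dataclasses.replace(SubjectConfig(), noise_sigma_pet=0.0, noise_sigma_blood=0.0)


@pytest.fixture(scope="session")
def noise_free_subject(noise_free_config):
    return generate_subject(noise_free_config)


@pytest.fixture(scope="session")
def default_subject():
    return generate_subject(dataclasses.replace(SubjectConfig(), seed=42))
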